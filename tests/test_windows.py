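"""Windowed FST/pi: examples, brute-force oracles, transform and outliers."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.io import MISSING, GenotypeMatrix, InputError, PopulationMap
from sweepscan.windows import (
    call_joint_outliers,
    compute_window_stats,
    pi_window,
    sliding_windows,
    transform_stats,
    wc_fst_window,
)

from conftest import random_genotype_matrix, two_group_popmap


# ---------------------------------------------------------------------------
# independent brute-force oracles (site-by-site, plain Python floats)
# ---------------------------------------------------------------------------


def oracle_wc_fst(geno_by_group: list[list[list[int]]]) -> tuple[float, float]:
    """Site-by-site Weir-Cockerham (1984) components, summed separately.

    ``geno_by_group[g][i]`` is the genotype column list of site ``i`` for
    group ``g``. Returns (sum_a, sum_abc). Written independently of the
    pipeline: explicit loops, no numpy.
    """
    r = 2
    n_sites = len(geno_by_group[0])
    sum_a = 0.0
    sum_all = 0.0
    for i in range(n_sites):
        stats = []
        for g in range(r):
            col = [x for x in geno_by_group[g][i] if x != MISSING]
            n = len(col)
            if n == 0:
                stats = None
                break
            p = sum(col) / (2 * n)
            h = sum(1 for x in col if x == 1) / n
            stats.append((n, p, h))
        if stats is None:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats
        nbar = (n1 + n2) / r
        if nbar <= 1:
            continue
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        if pbar == 0.0 or pbar == 1.0:
            continue
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sum_a += a
        sum_all += a + b + c
    return sum_a, sum_all


def oracle_pi(columns: list[list[int]], span: int) -> float:
    """Mean pairwise allele differences per bp, by explicit enumeration."""
    total = 0.0
    for col in columns:
        alleles = []
        for g in col:
            if g == MISSING:
                continue
            alleles.extend([1, 1] if g == 2 else ([0, 1] if g == 1 else [0, 0]))
        n = len(alleles)
        if n < 2:
            continue
        diffs = 0
        pairs = 0
        for i in range(n):
            for j in range(i + 1, n):
                pairs += 1
                diffs += alleles[i] != alleles[j]
        total += diffs / pairs
    return total / span


def _columns(gm: GenotypeMatrix, samples: list[str]) -> list[list[int]]:
    idx = gm.sample_indices(samples)
    return [gm.genotypes[idx, j].tolist() for j in range(gm.n_sites)]


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------


class TestSlidingWindows:
    def test_standard_overlapping(self):
        wins = sliding_windows(100_000, 50_000, 25_000)
        assert [w[0] for w in wins] == [0, 25_000, 50_000, 75_000]
        assert wins[-1] == (75_000, 100_000)

    def test_exact_length(self):
        wins = sliding_windows(50_000, 50_000, 25_000)
        assert wins == [(0, 50_000), (25_000, 50_000)]

    def test_non_overlapping_tiling(self):
        wins = sliding_windows(100_000, 25_000, 25_000)
        assert wins == [(0, 25_000), (25_000, 50_000), (50_000, 75_000),
                        (75_000, 100_000)]

    def test_invalid_params(self):
        with pytest.raises(InputError):
            sliding_windows(1000, 0, 10)
        with pytest.raises(InputError):
            sliding_windows(1000, 10, -5)
        with pytest.raises(InputError):
            sliding_windows(1000, 10, 20)


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------


class TestWcFst:
    def test_complete_fixation_is_one(self):
        genotypes = np.array(
            [[0]] * 4 + [[2]] * 4, dtype=np.int8
        )
        gm = GenotypeMatrix(
            "chr1", [100], [f"S{i}" for i in range(8)], genotypes
        )
        fst, n = wc_fst_window(gm, two_group_popmap(), (0, 1000))
        assert fst == pytest.approx(1.0)
        assert n == 1

    def test_monomorphic_window_is_nan(self):
        genotypes = np.zeros((8, 3), dtype=np.int8)
        gm = GenotypeMatrix(
            "chr1", [100, 200, 300], [f"S{i}" for i in range(8)], genotypes
        )
        fst, n = wc_fst_window(gm, two_group_popmap(), (0, 1000))
        assert np.isnan(fst)
        assert n == 0

    def test_three_groups_rejected(self):
        gm = random_genotype_matrix(np.random.default_rng(0), n_samples=6)
        pm = PopulationMap(
            {f"S{i}": f"g{i % 3}" for i in range(6)}
        )
        with pytest.raises(InputError, match="2"):
            wc_fst_window(gm, pm, (0, 1000))

    def test_tiny_fst_fixture_matches_oracle(self, tiny_fst):
        gm, pm = tiny_fst
        window = (0, 50_000)
        fst, _ = wc_fst_window(gm, pm, window)
        cols_a = _columns(gm, pm.samples_in("popA"))
        cols_b = _columns(gm, pm.samples_in("popB"))
        sum_a, sum_all = oracle_wc_fst([cols_a, cols_b])
        assert fst == pytest.approx(sum_a / sum_all, abs=1e-12)

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(4242)
        pm = two_group_popmap()
        for _ in range(100):
            gm = random_genotype_matrix(rng, n_samples=8, n_sites=20)
            window = (0, int(gm.positions[-1]))
            fst, _ = wc_fst_window(gm, pm, window)
            cols_a = _columns(gm, pm.samples_in("g1"))
            cols_b = _columns(gm, pm.samples_in("g2"))
            sum_a, sum_all = oracle_wc_fst([cols_a, cols_b])
            if sum_all == 0:
                assert np.isnan(fst)
            else:
                assert fst == pytest.approx(sum_a / sum_all, abs=1e-12)


# ---------------------------------------------------------------------------
# pi
# ---------------------------------------------------------------------------


class TestPiWindow:
    def test_no_segregating_sites(self):
        gm = GenotypeMatrix(
            "chr1", [100], ["a", "b"], np.zeros((2, 1), dtype=np.int8)
        )
        assert pi_window(gm, ["a", "b"], (0, 50_000)) == 0.0

    def test_single_site_closed_form(self):
        # alleles (0,0,1,1): pi = 2*0.5*0.5*(4/3) / 50000
        genotypes = np.array([[0], [2]], dtype=np.int8)
        gm = GenotypeMatrix("chr1", [100], ["a", "b"], genotypes)
        assert pi_window(gm, ["a", "b"], (0, 50_000)) == pytest.approx(
            (2 * 0.5 * 0.5 * 4 / 3) / 50_000, abs=1e-15
        )

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(777)
        for _ in range(100):
            gm = random_genotype_matrix(rng, n_samples=6, n_sites=20)
            span = int(gm.positions[-1])
            samples = gm.sample_ids[:4]
            got = pi_window(gm, samples, (0, span))
            expect = oracle_pi(_columns(gm, samples), span)
            assert got == pytest.approx(expect, abs=1e-12)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        gm = random_genotype_matrix(rng)
        samples = list(gm.sample_ids)
        w = (0, int(gm.positions[-1]))
        assert pi_window(gm, samples, w) == pi_window(gm, samples[::-1], w)

    def test_ref_alt_swap_invariance(self):
        rng = np.random.default_rng(5)
        gm = random_genotype_matrix(rng, missing_rate=0.0)
        w = (0, int(gm.positions[-1]))
        before = pi_window(gm, gm.sample_ids, w)
        swapped = GenotypeMatrix(
            gm.chrom, gm.positions, gm.sample_ids,
            (2 - gm.genotypes).astype(np.int8),
        )
        assert pi_window(swapped, gm.sample_ids, w) == pytest.approx(
            before, abs=1e-15
        )


# ---------------------------------------------------------------------------
# transforms and outliers
# ---------------------------------------------------------------------------


def _frame(fst, pi_obj=None, pi_ref=None):
    n = len(fst)
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "start": np.arange(n) * 25_000,
            "end": np.arange(n) * 25_000 + 50_000,
            "n_snps": [10] * n,
            "fst": fst,
            "pi_obj": pi_obj if pi_obj is not None else [1e-4] * n,
            "pi_ref": pi_ref if pi_ref is not None else [1e-4] * n,
        }
    )


class TestTransformStats:
    def test_z_example(self):
        df = transform_stats(_frame([0.1, 0.2, 0.3]))
        assert df["z_fst"].iloc[2] == pytest.approx(1.0)

    def test_z_mean_zero_sd_one(self):
        rng = np.random.default_rng(11)
        df = transform_stats(_frame(rng.uniform(0, 1, 200)))
        assert df["z_fst"].mean() == pytest.approx(0.0, abs=1e-9)
        assert df["z_fst"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_ratio_identities(self):
        df = transform_stats(
            _frame([0.1, 0.2], pi_obj=[1e-4, 1e-4], pi_ref=[1e-4, 2e-4])
        )
        assert df["log2_pi_ratio"].iloc[0] == pytest.approx(0.0)
        assert df["log2_pi_ratio"].iloc[1] == pytest.approx(1.0)

    def test_zero_pi_is_nan(self):
        df = transform_stats(
            _frame([0.1, 0.2], pi_obj=[0.0, 1e-4], pi_ref=[1e-4, 1e-4])
        )
        assert np.isnan(df["log2_pi_ratio"].iloc[0])

    def test_identical_fst_rejected(self):
        with pytest.raises(InputError):
            transform_stats(_frame([0.2, 0.2, 0.2]))


class TestJointOutliers:
    def test_absolute_mode_counts(self):
        rng = np.random.default_rng(8)
        fst = rng.uniform(0, 0.2, 100)
        pi_obj = np.full(100, 1e-4)
        pi_ref = np.full(100, 1e-4)
        # plant exactly 3 joint outliers at spaced windows
        for i in (10, 40, 70):
            fst[i] = 0.9
            pi_ref[i] = 16e-4  # log2 ratio 4
        df = transform_stats(_frame(fst, list(pi_obj), list(pi_ref)))
        flagged, _ = call_joint_outliers(
            df, mode="absolute", z_cut=2.0, ratio_cut=2.0
        )
        assert len(flagged) == 3

    def test_overlapping_windows_merge(self):
        df = transform_stats(
            _frame([0.9, 0.9, 0.1, 0.1], pi_ref=[4e-4, 4e-4, 1e-4, 1e-4])
        )
        flagged, regions = call_joint_outliers(
            df, mode="absolute", z_cut=0.5, ratio_cut=1.0
        )
        assert len(flagged) == 2
        assert regions == [("chr1", 0, 75_000)]

    def test_quantile_monotone_in_q(self):
        rng = np.random.default_rng(21)
        df = transform_stats(
            _frame(
                rng.uniform(0, 1, 200),
                list(rng.uniform(1e-5, 1e-4, 200)),
                list(rng.uniform(1e-5, 1e-4, 200)),
            )
        )
        prev: set = set()
        for q in (0.02, 0.05, 0.10, 0.25):
            flagged, _ = call_joint_outliers(df, q=q)
            cur = set(flagged.index)
            assert prev <= cur
            prev = cur

    def test_nan_windows_never_flagged(self):
        df = transform_stats(
            _frame([0.9, 0.1, 0.1], pi_obj=[0.0, 1e-4, 1e-4])
        )
        flagged, _ = call_joint_outliers(df, mode="absolute", z_cut=0.1,
                                         ratio_cut=-10, direction="high")
        assert 0 not in flagged.index


class TestComputeWindowStats:
    def test_shapes_and_columns(self, tiny_fst):
        gm, pm = tiny_fst
        df = compute_window_stats(
            {"chr1": gm}, pm, "popA", "popB", 5_000, 2_500,
            chrom_lengths={"chr1": 12_000},
        )
        assert list(df.columns) == [
            "chrom", "start", "end", "n_snps", "fst", "pi_obj", "pi_ref"
        ]
        assert df["n_snps"].sum() > 0
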