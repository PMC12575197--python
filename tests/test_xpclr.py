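"""XP-CLR scan: omega, weights, density normalization, score properties."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.io import GenotypeMatrix, InputError, PopulationMap
from sweepscan.xpclr import (
    XpclrConfig,
    estimate_omega,
    neutral_frequency_distribution,
    prepare_panel,
    snp_weights,
    xpclr_point,
    xpclr_scan,
)

from conftest import random_genotype_matrix, two_group_popmap


def _matrix_from_freqs(p_ref, p_obj, n_per_group=20, seed=0):
    """Build a matrix whose group frequencies are exactly as requested."""
    rng = np.random.default_rng(seed)
    n_sites = len(p_ref)
    cols = []
    for pr, po in zip(p_ref, p_obj):
        ref_alleles = _exact_alleles(pr, 2 * n_per_group)
        obj_alleles = _exact_alleles(po, 2 * n_per_group)
        col = np.concatenate(
            [
                obj_alleles.reshape(n_per_group, 2).sum(axis=1),
                ref_alleles.reshape(n_per_group, 2).sum(axis=1),
            ]
        )
        cols.append(col)
    genotypes = np.array(cols, dtype=np.int8).T
    samples = [f"O{i}" for i in range(n_per_group)] + [
        f"R{i}" for i in range(n_per_group)
    ]
    gm = GenotypeMatrix(
        "chr1",
        np.arange(1, n_sites + 1) * 1_000,
        samples,
        genotypes,
    )
    pm = PopulationMap(
        {s: ("fat" if s.startswith("O") else "thin") for s in samples}
    )
    return gm, pm


def _exact_alleles(p, n_alleles):
    k = round(p * n_alleles)
    return np.array([1] * k + [0] * (n_alleles - k))


class TestEstimateOmega:
    def test_identical_frequencies_give_zero(self):
        p = [0.25, 0.5, 0.75]
        gm, pm = _matrix_from_freqs(p, p)
        assert estimate_omega(gm, pm, "fat", "thin") == pytest.approx(0.0)

    def test_two_site_arithmetic(self):
        gm, pm = _matrix_from_freqs([0.5, 0.5], [0.6, 0.4])
        # mean(0.01/0.25, 0.01/0.25) = 0.04
        assert estimate_omega(gm, pm, "fat", "thin") == pytest.approx(0.04)

    def test_no_usable_sites_rejected(self):
        gm, pm = _matrix_from_freqs([0.0, 1.0], [0.5, 0.5])
        with pytest.raises(InputError):
            estimate_omega(gm, pm, "fat", "thin")

    def test_omega_grows_with_divergence_time(self):
        from scipy.stats import spearmanr

        from sweepscan.io import filter_snp_qc
        from sweepscan.simulate import SimulationConfig, simulate_two_pop

        means = []
        gens = [20, 60, 120]
        for split in gens:
            vals = []
            for seed in range(10):
                cfg = SimulationConfig(
                    n_diploids_per_pop=30, sequence_length=500_000,
                    n_sites=400, split_generations=split,
                    recombination_rate=7e-7, seed=seed,
                )
                mats, pm, _ = simulate_two_pop(cfg)
                vals.append(estimate_omega(mats, pm, "fat", "thin"))
            means.append(np.mean(vals))
        rho, _ = spearmanr(gens, means)
        assert rho > 0
        assert means[0] < means[-1]


class TestSnpWeights:
    def test_fully_correlated_cluster(self):
        g = np.tile(np.array([[0], [1], [2], [0], [2]]), (1, 3)).astype(np.int8)
        w = snp_weights(g, 0.95)
        assert w.tolist() == [1 / 3] * 3

    def test_uncorrelated_all_one(self, rng):
        g = rng.integers(0, 3, size=(40, 5)).astype(np.int8)
        w = snp_weights(g, 0.999999)
        assert w.tolist() == [1.0] * 5

    def test_mixed_clusters(self):
        rng = np.random.default_rng(123)
        base1 = rng.integers(0, 3, 50)
        base2 = rng.integers(0, 3, 50)
        base3 = rng.integers(0, 3, 50)
        g = np.column_stack([base1, base1, base2, base3, base3]).astype(np.int8)
        w = snp_weights(g, 0.95)
        assert w.tolist() == [0.5, 0.5, 1.0, 0.5, 0.5]

    def test_empty(self):
        assert snp_weights(np.empty((4, 0), dtype=np.int8)).size == 0


class TestNeutralDensity:
    @pytest.mark.parametrize("p1", [0.05, 0.2, 0.5, 0.8, 0.95])
    @pytest.mark.parametrize("omega", [1e-4, 0.01, 0.1, 0.5, 2.0])
    def test_normalization(self, p1, omega):
        _, mass, a0, a1 = neutral_frequency_distribution(p1, omega, 512)
        assert mass.sum() + a0 + a1 == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_sigma(self):
        _, mass, a0, a1 = neutral_frequency_distribution(0.5, 0.0, 64)
        assert mass.sum() + a0 + a1 == pytest.approx(1.0)
        assert mass.max() == 1.0


def _default_test_config(**kwargs):
    defaults = dict(
        grid_spacing=5_000, window_genetic_span=0.005,
        max_snps_per_window=50, morgans_per_bp=1e-7,
        quadrature_points=64,
    )
    defaults.update(kwargs)
    return XpclrConfig(**defaults)


class TestXpclrPoint:
    def test_identical_columns_score_zero(self):
        p = [0.2, 0.4, 0.6, 0.8, 0.3, 0.7]
        gm, pm = _matrix_from_freqs(p, p, seed=1)
        omega = max(estimate_omega(gm, pm, "fat", "thin"), 1e-4)
        config = _default_test_config()
        point = xpclr_point(gm, pm, 3_000, config, omega)
        assert point["score"] == pytest.approx(0.0, abs=1e-9)

    def test_neutral_s_matches_l0_termwise(self):
        # c == 1 for every SNP makes the sweep likelihood collapse to L0
        gm, pm = _matrix_from_freqs([0.3, 0.6], [0.5, 0.4])
        config = _default_test_config()
        panel = prepare_panel(gm, pm, "fat", "thin", config, omega=0.05)
        from sweepscan.xpclr import _score_window, _select_window

        idx, r = _select_window(panel, 1_500, config)
        weights = np.ones(len(idx))
        # replace the s grid with only the exact-neutral entry
        config.s_grid = np.array([0.0])
        score, s_hat = _score_window(panel, r, idx, weights, config)
        assert score == 0.0
        assert s_hat == 0.0

    def test_empty_window_emits_nan(self):
        gm, pm = _matrix_from_freqs([0.3], [0.6])
        config = _default_test_config()
        point = xpclr_point(gm, pm, 10_000_000, config, omega=0.05)
        assert np.isnan(point["score"])
        assert point["n_snps"] == 0

    def test_score_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(99)
        pm = two_group_popmap(10)
        config = _default_test_config()
        for trial in range(10):
            gm = random_genotype_matrix(rng, n_samples=20, n_sites=30)
            pm2 = PopulationMap(
                {s: ("g1" if i < 10 else "g2") for i, s in enumerate(gm.sample_ids)}
            )
            omega = max(estimate_omega(gm, pm2, "g1", "g2"), 1e-4)
            point = xpclr_point(
                gm, pm2, int(gm.positions[len(gm.positions) // 2]),
                config, omega, obj="g1", ref="g2",
            )
            assert point["score"] >= -1e-12

    def test_snp_order_invariance_of_selection(self):
        # the window selector must give identical results however SNPs are
        # fed, since the panel sorts by position internally
        rng = np.random.default_rng(17)
        gm = random_genotype_matrix(rng, n_samples=20, n_sites=25)
        pm = PopulationMap(
            {s: ("g1" if i < 10 else "g2") for i, s in enumerate(gm.sample_ids)}
        )
        omega = max(estimate_omega(gm, pm, "g1", "g2"), 1e-4)
        config = _default_test_config()
        p1 = xpclr_point(gm, pm, 120, config, omega, obj="g1", ref="g2")
        # shuffle sample order (site order is canonical by contract)
        order = rng.permutation(gm.n_samples)
        gm2 = GenotypeMatrix(
            gm.chrom, gm.positions,
            [gm.sample_ids[i] for i in order], gm.genotypes[order, :],
        )
        p2 = xpclr_point(gm2, pm, 120, config, omega, obj="g1", ref="g2")
        assert p1["score"] == pytest.approx(p2["score"], rel=1e-12)


class TestXpclrScan:
    def test_top_fraction_flagging_and_merge(self):
        rng = np.random.default_rng(5)
        config = _default_test_config(top_fraction=0.10, grid_spacing=2_000)
        gm = random_genotype_matrix(rng, n_samples=20, n_sites=60)
        pm = PopulationMap(
            {s: ("g1" if i < 10 else "g2") for i, s in enumerate(gm.sample_ids)}
        )
        points, regions = xpclr_scan(
            {"chr1": gm}, pm, config, obj="g1", ref="g2",
            chrom_lengths={"chr1": int(gm.positions[-1])},
        )
        scored = points["score"].dropna()
        n_flagged = (scored >= scored.quantile(0.90)).sum()
        assert n_flagged >= max(1, int(0.10 * len(scored)))
        for chrom, start, end in regions:
            assert end > start

    def test_quantile_flag_counts(self):
        # 1000 distinct scores -> exactly 10 at the 1% rule
        scores = pd.Series(np.arange(1000, dtype=float))
        thr = scores.quantile(0.99)
        assert (scores >= thr).sum() == 10

    def test_nonuniform_genetic_map(self, tmp_path):
        from sweepscan.xpclr import genetic_position, read_genetic_map

        path = tmp_path / "map.tsv"
        path.write_text(
            "chr1\t0\t0.0\nchr1\t100000\t0.001\nchr1\t200000\t0.005\n"
        )
        gmap = read_genetic_map(path)
        config = _default_test_config(genetic_map=gmap)
        got = genetic_position(np.array([50_000, 150_000]), "chr1", config)
        assert got == pytest.approx([0.0005, 0.003])
        # chromosomes absent from the map fall back to the uniform rate
        got2 = genetic_position(np.array([50_000]), "chr2", config)
        assert got2[0] == pytest.approx(50_000 * config.morgans_per_bp)

    def test_adjacent_flagged_points_merge(self):
        from sweepscan.intervals import merge_intervals

        regions = merge_intervals(
            [("chr1", 9_000, 11_000), ("chr1", 11_000, 13_000)]
        )
        assert regions == [("chr1", 9_000, 13_000)]
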