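"""Shared fixtures.

The heavy session-scoped replicate fixtures back the planted-sweep and
calibration acceptance criteria; they are computed lazily so that unit-only
runs stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from sweepscan.io import GenotypeMatrix, PopulationMap, filter_snp_qc
from sweepscan.simulate import (
    SimulationConfig,
    SweepSpec,
    _tiny_fst_matrix,
    simulate_two_pop,
    tile_genes,
)

# ---------------------------------------------------------------------------
# desk-scale simulation profile shared by acceptance + property tests
# ---------------------------------------------------------------------------

SEQ_LENGTH = 2_000_000
SWEEP_POS0 = 1_174_999  # 0-based; centered in GENE0010 [1125000, 1225000)
SWEEP_S = 0.1
TEST_SPLIT = 50
TEST_REC = 7e-7
N_REPLICATES = 20


def sweep_sim_config(seed: int, sweeps: bool = True) -> SimulationConfig:
    return SimulationConfig(
        n_diploids_per_pop=50,
        sequence_length=SEQ_LENGTH,
        n_sites=2_000,
        split_generations=TEST_SPLIT,
        recombination_rate=TEST_REC,
        sweeps=[SweepSpec(SWEEP_POS0, SWEEP_S)] if sweeps else [],
        seed=seed,
    )


def _analyse_replicate(seed: int, sweeps: bool) -> dict:
    """Simulate one replicate and run all three scans plus consensus."""
    from sweepscan import roh as sroh
    from sweepscan.consensus import consensus, regions_to_genes
    from sweepscan.windows import (
        call_joint_outliers,
        compute_window_stats,
        transform_stats,
    )
    from sweepscan.xpclr import XpclrConfig, estimate_omega, xpclr_scan

    matrices, pm, truths = simulate_two_pop(sweep_sim_config(seed, sweeps))
    matrices = {c: filter_snp_qc(g) for c, g in matrices.items()}
    lengths = {"chr1": SEQ_LENGTH}

    windows = transform_stats(
        compute_window_stats(matrices, pm, "fat", "thin", 100_000, 25_000, lengths)
    )
    _, fst_regions = call_joint_outliers(windows, q=0.12)

    xcfg = XpclrConfig(
        grid_spacing=10_000,
        window_genetic_span=0.07,
        max_snps_per_window=150,
        morgans_per_bp=TEST_REC,
        quadrature_points=64,
        top_fraction=0.02,
    )
    omega = estimate_omega(matrices, pm, "fat", "thin")
    points, xp_regions = xpclr_scan(
        matrices, pm, xcfg, omega=omega, chrom_lengths=lengths
    )

    params = sroh.RohParams(
        window_snps=25, max_het_per_window=1, max_missing_per_window=2,
        min_snps=50, min_length=100_000, max_gap=100_000, max_bp_per_snp=50_000,
    )
    segments, tracks, islands = sroh.roh_for_group(
        matrices, pm.samples_in("fat"), params, island_threshold_pct=30.0
    )

    genes = tile_genes(SEQ_LENGTH, 100_000, 25_000)
    report = consensus(
        {
            "fstpi": set(regions_to_genes(fst_regions, genes)),
            "xpclr": set(regions_to_genes(xp_regions, genes)),
            "roh": set(
                regions_to_genes(
                    [(i.chrom, i.start, i.end) for i in islands], genes
                )
            ),
        }
    )
    return {
        "matrices": matrices,
        "popmap": pm,
        "windows": windows,
        "fst_regions": fst_regions,
        "xpclr_points": points,
        "xpclr_regions": xp_regions,
        "omega": omega,
        "roh_segments": segments,
        "roh_islands": islands,
        "consensus": report,
    }


@pytest.fixture(scope="session")
def sweep_replicates() -> list[dict]:
    """Twenty seeded planted-sweep replicates, fully analysed."""
    return [_analyse_replicate(seed, sweeps=True) for seed in range(N_REPLICATES)]


@pytest.fixture(scope="session")
def neutral_replicates() -> list[dict]:
    """Twenty seeded neutral replicates, fully analysed."""
    return [
        _analyse_replicate(seed + 1000, sweeps=False)
        for seed in range(N_REPLICATES)
    ]


# ---------------------------------------------------------------------------
# small deterministic fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def tiny_fst():
    gm, pm = _tiny_fst_matrix()
    return gm, pm


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_genotype_matrix(
    rng: np.random.Generator,
    n_samples: int = 8,
    n_sites: int = 20,
    missing_rate: float = 0.05,
    chrom: str = "chr1",
) -> GenotypeMatrix:
    """Random matrix with guaranteed polymorphism and optional missingness."""
    positions = np.sort(rng.choice(np.arange(1, 10 * n_sites + 1), n_sites, replace=False))
    p = rng.uniform(0.1, 0.9, size=n_sites)
    genotypes = rng.binomial(1, p, size=(n_samples, n_sites)) + rng.binomial(
        1, p, size=(n_samples, n_sites)
    )
    mask = rng.random((n_samples, n_sites)) < missing_rate
    genotypes = np.where(mask, -1, genotypes).astype(np.int8)
    return GenotypeMatrix(
        chrom=chrom, positions=positions,
        sample_ids=[f"S{i}" for i in range(n_samples)],
        genotypes=genotypes,
    )


def two_group_popmap(n_per_group: int = 4) -> PopulationMap:
    names = [f"S{i}" for i in range(2 * n_per_group)]
    return PopulationMap(
        {s: ("g1" if i < n_per_group else "g2") for i, s in enumerate(names)}
    )
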