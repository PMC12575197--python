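"""Forward Wright-Fisher simulation of a two-population split with sweeps.

The simulator evolves diploid haplotype pools forward in time: an ancestral
pool is seeded with segregating sites drawn from a neutral (1/i) frequency
spectrum, the population splits into an object ("fat" proxy) and a
reference ("thin" proxy) group, and each then drifts independently.
Hard sweeps are planted in the object group by injecting a single copy of
a beneficial allele at the split and re-running the object group until the
allele fixes (conditioning on fixation). No new mutations arise after the
split, so both groups segregate a common site panel, as in a joint-called
VCF.

Gametes are formed with a Poisson number of crossovers at uniform physical
positions, so linkage, hitchhiking and runs of homozygosity emerge
physically rather than being painted on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from sweepscan.io import (
    GenotypeMatrix,
    GeneModel,
    PopulationMap,
    write_regions_bed,
    write_vcf,
)

__all__ = [
    "SweepSpec",
    "SweepTruth",
    "SimulationConfig",
    "SimulationError",
    "simulate_two_pop",
    "wright_fisher_generation",
    "seed_ancestral_pool",
    "tile_genes",
    "make_fixture_vcf",
]


class SimulationError(RuntimeError):
    """Raised when a conditioned sweep cannot be completed."""


@dataclass(frozen=True)
class SweepSpec:
    """A hard sweep to plant: physical position (bp, 0-based), selection
    coefficient ``s`` (het fitness 1+s, hom 1+2s) and target group label."""

    position: int
    s: float
    target: str = "fat"

    def __post_init__(self) -> None:
        if not 0.0 < self.s <= 1.0:
            raise ValueError("selection coefficient must be in (0, 1]")


@dataclass(frozen=True)
class SweepTruth:
    """Ground truth for one planted (and fixed) sweep."""

    chrom: str
    position: int  # 1-based VCF coordinate of the swept site
    s: float
    fixed: bool
    affected_window: tuple[int, int]  # 0-based half-open, expected signal span


@dataclass
class SimulationConfig:
    n_diploids_per_pop: int = 50
    sequence_length: int = 2_000_000
    n_sites: int = 2_000
    split_generations: int = 300
    recombination_rate: float = 1e-8  # Morgans per bp
    sweeps: list[SweepSpec] = field(default_factory=list)
    seed: int = 0
    n_chromosomes: int = 1
    object_group: str = "fat"
    reference_group: str = "thin"
    generation_cap_factor: int = 100
    affected_halfwidth: int = 100_000

    def __post_init__(self) -> None:
        if self.n_diploids_per_pop < 2:
            raise ValueError("need at least 2 diploids per population")
        if self.n_chromosomes not in (1, 2):
            raise ValueError("n_chromosomes must be 1 or 2")
        for sw in self.sweeps:
            if not 0 <= sw.position < self.sequence_length:
                raise ValueError("sweep position outside the sequence")
            if sw.target not in (self.object_group, self.reference_group):
                raise ValueError(f"sweep target {sw.target!r} is not a group label")


def seed_ancestral_pool(
    n_haplotypes: int, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """Seed an ancestral haplotype pool from a neutral frequency spectrum.

    Each site receives a derived-allele count ``i`` in ``1..n_haplotypes-1``
    with probability proportional to ``1/i``, assigned to random haplotypes.
    """
    counts = np.arange(1, n_haplotypes)
    probs = (1.0 / counts) / (1.0 / counts).sum()
    H = np.zeros((n_haplotypes, n_sites), dtype=np.int8)
    draws = rng.choice(counts, size=n_sites, p=probs)
    for j, i in enumerate(draws):
        carriers = rng.choice(n_haplotypes, size=i, replace=False)
        H[carriers, j] = 1
    return H


def wright_fisher_generation(
    H: np.ndarray,
    positions: np.ndarray,
    sequence_length: int,
    recombination_rate: float,
    rng: np.random.Generator,
    fitness: np.ndarray | None = None,
) -> np.ndarray:
    """One generation of random union of gametes with recombination.

    ``H`` has shape ``(2N, n_sites)``; individual ``j`` owns rows ``2j`` and
    ``2j+1``. Each offspring haplotype is a gamete from an independently
    chosen parent (chosen proportionally to ``fitness`` when given), built
    from the parent's two strands with ``Poisson(rate * length)`` crossovers
    at uniform physical positions.
    """
    n_hap, n_sites = H.shape
    n_ind = n_hap // 2
    if fitness is None:
        parents = rng.integers(0, n_ind, size=n_hap)
    else:
        parents = rng.choice(n_ind, size=n_hap, p=fitness / fitness.sum())
    strands = rng.integers(0, 2, size=n_hap)
    n_cross = rng.poisson(recombination_rate * sequence_length, size=n_hap)

    child = H[2 * parents + strands].copy()
    for g in np.flatnonzero(n_cross):
        cuts = rng.uniform(0.0, sequence_length, size=n_cross[g])
        cut_idx = np.searchsorted(positions, np.sort(cuts))
        flips = np.zeros(n_sites + 1, dtype=np.int64)
        np.add.at(flips, cut_idx, 1)
        other = (np.cumsum(flips[:n_sites]) % 2).astype(bool)
        if other.any():
            child[g, other] = H[2 * parents[g] + (1 - strands[g]), other]
    return child


def _sweep_fitness(H: np.ndarray, sweep_cols: np.ndarray, s_values: np.ndarray) -> np.ndarray:
    """Multiplicative diploid fitness 1, 1+s, 1+2s at each sweep site."""
    n_ind = H.shape[0] // 2
    dosage = H[0::2][:, sweep_cols].astype(np.float64) + H[1::2][:, sweep_cols]
    return np.prod(1.0 + s_values * dosage, axis=1).reshape(n_ind)


def simulate_two_pop(
    config: SimulationConfig,
) -> tuple[dict[str, GenotypeMatrix], PopulationMap, list[SweepTruth]]:
    """Simulate the two-group contrast and return merged genotype matrices.

    Returns per-chromosome :class:`GenotypeMatrix` objects holding both
    groups' samples, the matching :class:`PopulationMap`, and the list of
    :class:`SweepTruth` records (all sweeps conditioned on fixation).
    """
    rng = np.random.default_rng(config.seed)
    n_hap = 2 * config.n_diploids_per_pop
    L = config.sequence_length

    # site panel: unique 1-based positions; sweep sites injected explicitly
    sweep_pos1 = [sw.position + 1 for sw in config.sweeps]
    if len(set(sweep_pos1)) != len(sweep_pos1):
        raise ValueError("sweep positions must be distinct")
    taken = set(sweep_pos1)
    neutral_pos: set[int] = set()
    while len(neutral_pos) < config.n_sites:
        cand = rng.integers(1, L + 1, size=config.n_sites - len(neutral_pos))
        neutral_pos.update(int(p) for p in cand if p not in taken)
    positions = np.array(sorted(neutral_pos | taken), dtype=np.int64)
    sweep_cols = np.searchsorted(positions, np.array(sweep_pos1, dtype=np.int64))

    ancestral = seed_ancestral_pool(n_hap, len(positions), rng)
    ancestral[:, sweep_cols] = 0  # beneficial alleles are new at the split

    pops: dict[str, np.ndarray] = {}
    for group in (config.object_group, config.reference_group):
        specs = [sw for sw in config.sweeps if sw.target == group]
        if not specs:
            H = ancestral.copy()
            for _ in range(config.split_generations):
                H = wright_fisher_generation(
                    H, positions, L, config.recombination_rate, rng
                )
            pops[group] = H
        else:
            pops[group] = _evolve_with_sweeps(
                ancestral, positions, config, specs, sweep_cols, rng
            )

    truths = [
        SweepTruth(
            chrom=_chrom_of(sw.position + 1, config),
            position=_local_pos(sw.position + 1, config),
            s=sw.s,
            fixed=True,
            affected_window=(
                max(0, _local_pos(sw.position + 1, config) - 1 - config.affected_halfwidth),
                _local_pos(sw.position + 1, config) - 1 + config.affected_halfwidth,
            ),
        )
        for sw in config.sweeps
    ]

    obj_ids = [f"{config.object_group}_{i + 1:03d}" for i in range(config.n_diploids_per_pop)]
    ref_ids = [f"{config.reference_group}_{i + 1:03d}" for i in range(config.n_diploids_per_pop)]
    genotypes = np.vstack(
        [
            _diploid_genotypes(pops[config.object_group]),
            _diploid_genotypes(pops[config.reference_group]),
        ]
    )
    sample_ids = obj_ids + ref_ids
    popmap = PopulationMap(
        {**{s: config.object_group for s in obj_ids},
         **{s: config.reference_group for s in ref_ids}}
    )

    matrices: dict[str, GenotypeMatrix] = {}
    for chrom, site_mask, offset in _chromosome_slices(positions, config):
        n_sites = int(site_mask.sum())
        matrices[chrom] = GenotypeMatrix(
            chrom=chrom,
            positions=positions[site_mask] - offset,
            sample_ids=sample_ids,
            genotypes=genotypes[:, site_mask],
            qd=np.full(n_sites, 30.0),
            mq=np.full(n_sites, 60.0),
            fs=np.full(n_sites, 0.5),
            depth=np.full(n_sites, 15.0),
        )
    return matrices, popmap, truths


def _evolve_with_sweeps(
    ancestral: np.ndarray,
    positions: np.ndarray,
    config: SimulationConfig,
    specs: list[SweepSpec],
    all_sweep_cols: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve one population with selection, restarting until all sweeps fix.

    Attempts where any beneficial allele is lost, or where any remains
    segregating at sampling time, are rejected and re-run from the split
    state with fresh randomness. A total generation budget of
    ``generation_cap_factor * split_generations`` bounds the rejection loop.
    """
    sweep_pos1 = np.array([sw.position + 1 for sw in specs], dtype=np.int64)
    cols = np.searchsorted(positions, sweep_pos1)
    s_values = np.array([sw.s for sw in specs])
    n_hap = ancestral.shape[0]
    budget = config.generation_cap_factor * config.split_generations
    spent = 0

    while True:
        H = ancestral.copy()
        for c in cols:
            H[rng.integers(0, n_hap), c] = 1
        ok = True
        for _ in range(config.split_generations):
            fitness = _sweep_fitness(H, cols, s_values)
            H = wright_fisher_generation(
                H, positions, config.sequence_length,
                config.recombination_rate, rng, fitness=fitness,
            )
            spent += 1
            freqs = H[:, cols].sum(axis=0)
            if np.any(freqs == 0):
                ok = False
                break
        if ok and np.all(H[:, cols].sum(axis=0) == n_hap):
            return H
        if spent >= budget:
            raise SimulationError(
                "sweep failed to fix within the generation budget "
                f"({budget} generations); consider a larger selection "
                "coefficient or more split generations"
            )


def _diploid_genotypes(H: np.ndarray) -> np.ndarray:
    return (H[0::2] + H[1::2]).astype(np.int8)


def _chromosome_slices(positions: np.ndarray, config: SimulationConfig):
    if config.n_chromosomes == 1:
        yield "chr1", np.ones(len(positions), dtype=bool), 0
    else:
        half = config.sequence_length // 2
        left = positions <= half
        yield "chr1", left, 0
        yield "chr2", ~left, half


def _chrom_of(pos1: int, config: SimulationConfig) -> str:
    if config.n_chromosomes == 1 or pos1 <= config.sequence_length // 2:
        return "chr1"
    return "chr2"


def _local_pos(pos1: int, config: SimulationConfig) -> int:
    if config.n_chromosomes == 2 and pos1 > config.sequence_length // 2:
        return pos1 - config.sequence_length // 2
    return pos1


# ---------------------------------------------------------------------------
# gene tiling
# ---------------------------------------------------------------------------


def tile_genes(
    sequence_length: int,
    gene_size: int,
    gap: int,
    chrom: str = "chr1",
    bed_path: str | Path | None = None,
) -> list[GeneModel]:
    """Tile genes GENE0001, GENE0002, ... left to right along a chromosome.

    Genes are ``gene_size`` bp long and separated by ``gap`` bp; a trailing
    gene is clipped at the sequence end. Optionally writes a BED file.
    """
    if gene_size <= 0 or gap <= 0:
        raise ValueError("gene_size and gap must be positive")
    genes: list[GeneModel] = []
    start = 0
    i = 1
    while start < sequence_length:
        end = min(start + gene_size, sequence_length)
        genes.append(GeneModel(f"GENE{i:04d}", chrom, start, end, "+"))
        start += gene_size + gap
        i += 1
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for g in genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    return genes


# ---------------------------------------------------------------------------
# deterministic unit-test fixtures
# ---------------------------------------------------------------------------

# tiny_fst: 8 samples (A* vs B*), 12 sites with assorted frequencies,
# a fixed difference (site 4), a monomorphic site (site 8) and one
# missing call (sample A2, site 6).
_TINY_FST_GENOTYPES = np.array(
    [
        # sites:  1  2  3  4  5  6  7  8  9 10 11 12
        [0, 1, 2, 0, 1, 0, 2, 0, 1, 2, 0, 1],  # A1
        [0, 1, 1, 0, 0, -1, 2, 0, 1, 1, 0, 0],  # A2
        [1, 0, 2, 0, 1, 1, 1, 0, 0, 2, 1, 1],  # A3
        [0, 1, 2, 0, 0, 0, 2, 0, 1, 2, 0, 2],  # A4
        [2, 1, 0, 2, 1, 2, 0, 0, 2, 0, 1, 1],  # B1
        [1, 2, 0, 2, 2, 2, 0, 0, 1, 0, 2, 2],  # B2
        [2, 1, 1, 2, 1, 1, 1, 0, 2, 1, 1, 1],  # B3
        [2, 2, 0, 2, 2, 2, 0, 0, 2, 0, 2, 2],  # B4
    ],
    dtype=np.int8,
)


def _tiny_fst_matrix() -> tuple[GenotypeMatrix, PopulationMap]:
    samples = ["A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4"]
    gm = GenotypeMatrix(
        chrom="chr1",
        positions=np.arange(1, 13) * 1000,
        sample_ids=samples,
        genotypes=_TINY_FST_GENOTYPES,
    )
    pm = PopulationMap({s: ("popA" if s.startswith("A") else "popB") for s in samples})
    return gm, pm


def _roh_toy_matrix() -> tuple[GenotypeMatrix, PopulationMap]:
    # I1 is homozygous over a 1 Mb block (40 SNPs, 100 kb .. 1.075 Mb pitch
    # 25 kb) flanked by heterozygous sites; I2 is heterozygous throughout.
    flank_left = np.arange(10_000, 60_000, 10_000)
    block = 100_000 + 25_000 * np.arange(40)
    flank_right = np.arange(1_150_000, 1_200_000, 10_000)
    positions = np.concatenate([flank_left, block, flank_right])
    i1 = np.concatenate(
        [np.ones(5, dtype=np.int8),
         np.full(40, 2, dtype=np.int8),
         np.ones(5, dtype=np.int8)]
    )
    i2 = np.ones(50, dtype=np.int8)
    gm = GenotypeMatrix(
        chrom="chr1",
        positions=positions,
        sample_ids=["I1", "I2"],
        genotypes=np.vstack([i1, i2]),
    )
    return gm, PopulationMap({"I1": "fat", "I2": "fat"})


def _filter_toy_matrix() -> GenotypeMatrix:
    # 10 samples x 10 sites; exactly 4 sites violate quality thresholds:
    #   site 3: QD = 1.5 (< 2.0)         site 5: MQ = 19 (< 20)
    #   site 7: FS = 60.5 (> 60.0)       site 9: MAF = 0.05 exactly
    # boundary-value sites (QD=2.0, MQ=20, FS=60.0, call rate > 0.9) pass.
    n = 10
    genotypes = np.zeros((n, 10), dtype=np.int8)
    for j in range(10):
        genotypes[: 2 + (j % 3), j] = 1  # MAF 0.10-0.20
    genotypes[:, 8] = 0
    genotypes[0, 8] = 1  # 1/20 alleles -> MAF exactly 0.05
    qd = np.full(10, 25.0)
    qd[2] = 1.5
    qd[0] = 2.0  # boundary: kept
    mq = np.full(10, 60.0)
    mq[4] = 19.0
    mq[1] = 20.0  # boundary: kept
    fs = np.full(10, 1.0)
    fs[6] = 60.5
    fs[3] = 60.0  # boundary: kept
    return GenotypeMatrix(
        chrom="chr1",
        positions=np.arange(1, 11) * 100,
        sample_ids=[f"S{i + 1}" for i in range(n)],
        genotypes=genotypes,
        qd=qd,
        mq=mq,
        fs=fs,
        depth=np.full(10, 15.0),
    )


def make_fixture_vcf(name: str, outdir: str | Path) -> dict[str, Path]:
    """Write one of the deterministic hand-constructed test datasets.

    ``tiny_fst``, ``roh_toy`` and ``filter_toy`` emit a VCF (+ popmap where
    meaningful); ``enrich_toy`` emits a gene->term annotation TSV and a
    candidate gene list. Returns the written paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "tiny_fst":
        gm, pm = _tiny_fst_matrix()
        vcf = outdir / "tiny_fst.vcf"
        popmap = outdir / "tiny_fst.popmap.tsv"
        write_vcf({"chr1": gm}, vcf)
        pm.write(popmap)
        return {"vcf": vcf, "popmap": popmap}
    if name == "roh_toy":
        gm, pm = _roh_toy_matrix()
        vcf = outdir / "roh_toy.vcf"
        popmap = outdir / "roh_toy.popmap.tsv"
        write_vcf({"chr1": gm}, vcf)
        pm.write(popmap)
        return {"vcf": vcf, "popmap": popmap}
    if name == "filter_toy":
        gm = _filter_toy_matrix()
        vcf = outdir / "filter_toy.vcf"
        write_vcf({"chr1": gm}, vcf)
        return {"vcf": vcf}
    if name == "enrich_toy":
        ann = outdir / "enrich_toy.annotation.tsv"
        cand = outdir / "enrich_toy.candidates.txt"
        with open(ann, "w") as fh:
            for g in ["G01", "G02", "G03", "G10", "G11"]:
                fh.write(f"{g}\tT1\tterm one\n")
            for g in ["G04", "G05", "G12", "G13", "G14", "G15"]:
                fh.write(f"{g}\tT2\tterm two\n")
            for i in range(1, 21):
                fh.write(f"G{i:02d}\tT3\tterm three\n")
            fh.write("G06\tT4\tsingleton term\n")
        with open(cand, "w") as fh:
            fh.write("\n".join(["G01", "G02", "G03", "G04", "G05"]) + "\n")
        return {"annotation": ann, "candidates": cand}
    raise ValueError(f"unknown fixture {name!r}")
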