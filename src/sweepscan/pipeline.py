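"""End-to-end run orchestration: simulate/load -> QC -> three scans ->
consensus -> enrichment, with TOML config validation, resume and a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import sweepscan
from sweepscan import io as sio
from sweepscan import roh as sroh
from sweepscan.consensus import consensus, regions_to_genes
from sweepscan.enrichment import enrich, read_annotation
from sweepscan.simulate import SimulationConfig, SweepSpec, simulate_two_pop, tile_genes
from sweepscan.windows import call_joint_outliers, compute_window_stats, transform_stats
from sweepscan.xpclr import XpclrConfig, estimate_omega, xpclr_scan

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass
class RunConfig:
    seed: int = 0
    object_group: str = "fat"
    reference_group: str = "thin"
    # inputs; when vcf is None the simulate stage provides the data
    vcf: str | None = None
    popmap: str | None = None
    genes: str | None = None
    annotation: str | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    # stage parameter blocks
    simulate: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    fstpi: dict = field(default_factory=dict)
    xpclr: dict = field(default_factory=dict)
    roh: dict = field(default_factory=dict)
    consensus: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=dict)


_FILTER_DEFAULTS = dict(
    qd_min=2.0, mq_min=20.0, fs_max=60.0,
    call_rate_min=0.9, maf_min=0.05, depth_min=3.0, depth_max=30.0,
)
_FSTPI_DEFAULTS = dict(
    window=50_000, step=25_000, mode="quantile", q=0.05,
    z_cut=1.58, ratio_cut=0.24, direction="high",
)
_XPCLR_DEFAULTS = dict(
    grid_spacing=2_000, window_genetic_span=0.005, max_snps_per_window=200,
    corr_threshold=0.95, morgans_per_bp=1e-8, quadrature_points=512,
    top_fraction=0.01, s_grid_size=12,
)
_ROH_DEFAULTS = dict(
    preset="plink", island_threshold=20.0,
    window_snps=None, max_het_per_window=None, max_missing_per_window=None,
    min_snps=None, min_length=None, max_gap=None, max_bp_per_snp=None,
)
_SIM_DEFAULTS = dict(
    n_diploids_per_pop=50, sequence_length=2_000_000, n_sites=2_000,
    split_generations=300, recombination_rate=1e-8, n_chromosomes=1,
    sweep_positions=[], sweep_s=[],
)
_CONSENSUS_DEFAULTS = dict(flank=0)
_ENRICH_DEFAULTS = dict(alpha=0.05, n_terms=8)

_SECTIONS = {
    "simulate": _SIM_DEFAULTS,
    "filter": _FILTER_DEFAULTS,
    "fstpi": _FSTPI_DEFAULTS,
    "xpclr": _XPCLR_DEFAULTS,
    "roh": _ROH_DEFAULTS,
    "consensus": _CONSENSUS_DEFAULTS,
    "enrich": _ENRICH_DEFAULTS,
}
_TOP_KEYS = {
    "seed", "object_group", "reference_group",
    "vcf", "popmap", "genes", "annotation", "chrom_lengths",
}


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration.

    All problems are aggregated into one :class:`ConfigError`; unknown
    keys are rejected, defaults are filled, and referenced files must
    exist.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    errors: list[str] = []

    cfg = RunConfig()
    for key in list(raw):
        if key in _TOP_KEYS:
            setattr(cfg, key, raw.pop(key))
        elif key in _SECTIONS:
            continue
        else:
            errors.append(f"unknown top-level key {key!r}")
            raw.pop(key)

    for section, defaults in _SECTIONS.items():
        block = raw.pop(section, {})
        if not isinstance(block, dict):
            errors.append(f"section [{section}] must be a table")
            block = {}
        merged = dict(defaults)
        for key, value in block.items():
            if key not in defaults:
                errors.append(f"unknown key {section}.{key}")
            else:
                merged[key] = value
        setattr(cfg, section, merged)

    if not isinstance(cfg.seed, int):
        errors.append("seed must be an integer")
    if cfg.object_group == cfg.reference_group:
        errors.append("object_group and reference_group must differ")
    for name in ("vcf", "popmap", "genes", "annotation"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            errors.append(f"{name} path does not exist: {p}")
    if cfg.vcf is not None and cfg.popmap is None:
        errors.append("popmap is required when vcf is given")

    def check_pos(section: str, key: str) -> None:
        v = getattr(cfg, section).get(key)
        if v is not None and (not isinstance(v, (int, float)) or v <= 0):
            errors.append(f"{section}.{key} must be positive (got {v!r})")

    for key in ("window", "step"):
        check_pos("fstpi", key)
    for key in ("grid_spacing", "window_genetic_span", "max_snps_per_window",
                "quadrature_points", "morgans_per_bp"):
        check_pos("xpclr", key)
    for key in ("n_diploids_per_pop", "sequence_length", "n_sites",
                "split_generations"):
        check_pos("simulate", key)
    if cfg.fstpi["mode"] not in ("quantile", "absolute"):
        errors.append("fstpi.mode must be 'quantile' or 'absolute'")
    if not 0 < cfg.fstpi["q"] < 1:
        errors.append("fstpi.q must be in (0, 1)")
    if not 0 < cfg.xpclr["top_fraction"] < 1:
        errors.append("xpclr.top_fraction must be in (0, 1)")
    if cfg.roh["preset"] not in sroh.PRESETS:
        errors.append(
            f"roh.preset must be one of {sorted(sroh.PRESETS)}"
        )
    if len(cfg.simulate["sweep_positions"]) != len(cfg.simulate["sweep_s"]):
        errors.append("simulate.sweep_positions and sweep_s differ in length")

    if errors:
        raise ConfigError(errors)
    return cfg


def _roh_params(cfg: RunConfig) -> sroh.RohParams:
    base = sroh.PRESETS[cfg.roh["preset"]]
    overrides = {
        k: v
        for k, v in cfg.roh.items()
        if k not in ("preset", "island_threshold") and v is not None
    }
    from dataclasses import replace

    return replace(base, **overrides)


def _hash_config(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_all(cfg: RunConfig, outdir: str | Path, resume: bool = True) -> dict:
    """Execute all pipeline stages into ``outdir`` and write a manifest.

    A stage is skipped when resuming and all its output files already
    exist. Returns the manifest dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": sweepscan.__version__,
        "config_hash": _hash_config(cfg),
        "seed": cfg.seed,
        "stages": {},
    }
    logger.info("run_all: seed=%d outdir=%s", cfg.seed, outdir)

    def stage(name: str, outputs: list[Path], fn) -> None:
        t0 = time.perf_counter()
        if resume and outputs and all(p.exists() for p in outputs):
            logger.info("stage %s: outputs exist, skipped (resume)", name)
            manifest["stages"][name] = {"skipped": True}
            return
        counts = fn()
        manifest["stages"][name] = {
            "skipped": False,
            "seconds": round(time.perf_counter() - t0, 3),
            **(counts or {}),
        }
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

    # --- data acquisition -------------------------------------------------
    sim_dir = outdir / "simulate"
    if cfg.vcf is None:
        vcf_path = sim_dir / "sim.vcf"
        popmap_path = sim_dir / "popmap.tsv"
        genes_path = sim_dir / "genes.bed"
        truth_path = sim_dir / "truth.tsv"

        def do_simulate():
            sim_dir.mkdir(exist_ok=True)
            sc = cfg.simulate
            sweeps = [
                SweepSpec(position=int(p), s=float(s), target=cfg.object_group)
                for p, s in zip(sc["sweep_positions"], sc["sweep_s"])
            ]
            sim = SimulationConfig(
                n_diploids_per_pop=sc["n_diploids_per_pop"],
                sequence_length=sc["sequence_length"],
                n_sites=sc["n_sites"],
                split_generations=sc["split_generations"],
                recombination_rate=sc["recombination_rate"],
                n_chromosomes=sc["n_chromosomes"],
                sweeps=sweeps,
                seed=cfg.seed,
                object_group=cfg.object_group,
                reference_group=cfg.reference_group,
            )
            matrices, pm, truths = simulate_two_pop(sim)
            sio.write_vcf(matrices, vcf_path)
            pm.write(popmap_path)
            if cfg.genes is None:
                tile_genes(
                    sc["sequence_length"] if sc["n_chromosomes"] == 1
                    else sc["sequence_length"] // 2,
                    gene_size=100_000, gap=25_000, bed_path=genes_path,
                )
            sio.write_table_tsv(
                pd.DataFrame(
                    [
                        {
                            "chrom": t.chrom, "position": t.position,
                            "s": t.s, "fixed": t.fixed,
                        }
                        for t in truths
                    ],
                    columns=["chrom", "position", "s", "fixed"],
                ),
                truth_path,
            )
            return {"n_sites": sum(g.n_sites for g in matrices.values())}

        sim_outputs = [vcf_path, popmap_path, truth_path]
        if cfg.genes is None:
            sim_outputs.append(genes_path)
        stage("simulate", sim_outputs, do_simulate)
        if cfg.genes is None:
            cfg_genes = genes_path
        else:
            cfg_genes = Path(cfg.genes)
    else:
        vcf_path = Path(cfg.vcf)
        popmap_path = Path(cfg.popmap)
        if cfg.genes is None:
            raise ConfigError(["genes annotation is required with an input VCF"])
        cfg_genes = Path(cfg.genes)

    # --- QC filtering -----------------------------------------------------
    filt_dir = outdir / "filter"
    filtered_vcf = filt_dir / "filtered.vcf"

    def do_filter():
        filt_dir.mkdir(exist_ok=True)
        result = sio.read_vcf(vcf_path)
        out = {}
        before = after = 0
        for chrom, gm in result.matrices.items():
            before += gm.n_sites
            f = cfg.filter
            gm = sio.filter_variant_quality(
                gm, f["qd_min"], f["mq_min"], f["fs_max"]
            )
            gm = sio.filter_snp_qc(
                gm, f["call_rate_min"], f["maf_min"],
                f["depth_min"], f["depth_max"],
            )
            after += gm.n_sites
            out[chrom] = gm
        sio.write_vcf(out, filtered_vcf)
        return {"sites_in": before, "sites_out": after}

    stage("filter", [filtered_vcf], do_filter)

    # shared inputs for the scans
    matrices = sio.read_vcf(filtered_vcf).matrices
    pm = sio.PopulationMap.read(popmap_path)
    obj, ref = cfg.object_group, cfg.reference_group
    chrom_lengths = {k: int(v) for k, v in cfg.chrom_lengths.items()} or None
    if chrom_lengths is None and cfg.vcf is None:
        L = cfg.simulate["sequence_length"]
        if cfg.simulate["n_chromosomes"] == 2:
            chrom_lengths = {"chr1": L // 2, "chr2": L - L // 2}
        else:
            chrom_lengths = {"chr1": L}

    # --- FST / pi ---------------------------------------------------------
    fst_dir = outdir / "fstpi"
    windows_tsv = fst_dir / "windows.tsv"
    fst_regions_bed = fst_dir / "outlier_regions.bed"
    fst_flagged_tsv = fst_dir / "outlier_windows.tsv"

    def do_fstpi():
        fst_dir.mkdir(exist_ok=True)
        f = cfg.fstpi
        df = compute_window_stats(
            matrices, pm, obj, ref, f["window"], f["step"], chrom_lengths
        )
        df = transform_stats(df)
        flagged, regions = call_joint_outliers(
            df, mode=f["mode"], z_cut=f["z_cut"], ratio_cut=f["ratio_cut"],
            q=f["q"], direction=f["direction"],
        )
        sio.write_table_tsv(df, windows_tsv)
        sio.write_table_tsv(flagged, fst_flagged_tsv)
        sio.write_regions_bed(regions, fst_regions_bed)
        return {"n_windows": len(df), "n_flagged": len(flagged),
                "n_regions": len(regions)}

    stage("fstpi", [windows_tsv, fst_regions_bed, fst_flagged_tsv], do_fstpi)

    # --- XP-CLR -----------------------------------------------------------
    xp_dir = outdir / "xpclr"
    xp_points_tsv = xp_dir / "points.tsv"
    xp_regions_bed = xp_dir / "regions.bed"

    def do_xpclr():
        xp_dir.mkdir(exist_ok=True)
        x = cfg.xpclr
        xconfig = XpclrConfig(
            grid_spacing=x["grid_spacing"],
            window_genetic_span=x["window_genetic_span"],
            max_snps_per_window=x["max_snps_per_window"],
            corr_threshold=x["corr_threshold"],
            morgans_per_bp=x["morgans_per_bp"],
            quadrature_points=x["quadrature_points"],
            top_fraction=x["top_fraction"],
        )
        omega = estimate_omega(matrices, pm, obj, ref)
        points, regions = xpclr_scan(
            matrices, pm, xconfig, obj, ref, omega=omega,
            chrom_lengths=chrom_lengths,
        )
        points.to_csv(xp_points_tsv, sep="\t", index=False, float_format="%.10g")
        sio.write_regions_bed(regions, xp_regions_bed)
        return {"omega": omega, "n_points": len(points), "n_regions": len(regions)}

    stage("xpclr", [xp_points_tsv, xp_regions_bed], do_xpclr)

    # --- ROH --------------------------------------------------------------
    roh_dir = outdir / "roh"
    roh_segments_tsv = roh_dir / "segments.tsv"
    roh_track_tsv = roh_dir / "occurrence.tsv"
    roh_islands_bed = roh_dir / "islands.bed"
    roh_islands_tsv = roh_dir / "islands.tsv"

    def do_roh():
        roh_dir.mkdir(exist_ok=True)
        params = _roh_params(cfg)
        group_samples = pm.samples_in(obj)
        segments, tracks, islands = sroh.roh_for_group(
            matrices, group_samples, params, cfg.roh["island_threshold"]
        )
        sio.write_table_tsv(
            pd.DataFrame(
                [
                    {"sample_id": s.sample_id, "chrom": s.chrom,
                     "start": s.start, "end": s.end,
                     "n_snps": s.n_snps, "length": s.length}
                    for s in segments
                ],
                columns=["sample_id", "chrom", "start", "end", "n_snps", "length"],
            ),
            roh_segments_tsv,
        )
        track_rows = []
        for chrom, gm in matrices.items():
            for pos, pct in zip(gm.positions, tracks[chrom]):
                track_rows.append(
                    {"chrom": chrom, "position": int(pos), "occurrence_pct": pct}
                )
        pd.DataFrame(
            track_rows, columns=["chrom", "position", "occurrence_pct"]
        ).to_csv(roh_track_tsv, sep="\t", index=False, float_format="%.10g")
        sio.write_table_tsv(
            pd.DataFrame(
                [
                    {"chrom": i.chrom, "start": i.start, "end": i.end,
                     "peak_occurrence_pct": i.peak_occurrence_pct,
                     "mean_occurrence_pct": i.mean_occurrence_pct,
                     "n_snps": i.n_snps}
                    for i in islands
                ],
                columns=["chrom", "start", "end", "peak_occurrence_pct",
                         "mean_occurrence_pct", "n_snps"],
            ),
            roh_islands_tsv,
        )
        sio.write_regions_bed([(i.chrom, i.start, i.end) for i in islands],
                              roh_islands_bed)
        return {"n_segments": len(segments), "n_islands": len(islands)}

    stage("roh", [roh_segments_tsv, roh_track_tsv, roh_islands_bed,
                  roh_islands_tsv], do_roh)

    # --- consensus --------------------------------------------------------
    cons_dir = outdir / "consensus"
    venn_tsv = cons_dir / "venn.tsv"
    consensus_txt = cons_dir / "consensus_genes.txt"

    def do_consensus():
        cons_dir.mkdir(exist_ok=True)
        genes = sio.read_gene_annotation(cfg_genes)
        flank = cfg.consensus["flank"]
        sets = {}
        for name, bed in (
            ("fstpi", fst_regions_bed),
            ("xpclr", xp_regions_bed),
            ("roh", roh_islands_bed),
        ):
            regions = sio.read_regions_bed(bed)
            sets[name] = set(regions_to_genes(regions, genes, flank=flank))
        report = consensus(sets)
        rows = [
            {"cell": cell, "count": len(members),
             "genes": "|".join(sorted(members))}
            for cell, members in sorted(report.cells.items())
        ]
        pd.DataFrame(rows, columns=["cell", "count", "genes"]).to_csv(
            venn_tsv, sep="\t", index=False
        )
        with open(consensus_txt, "w") as fh:
            fh.write("\n".join(report.triple) + ("\n" if report.triple else ""))
        return {"n_consensus": len(report.triple),
                "n_union": len(report.union)}

    stage("consensus", [venn_tsv, consensus_txt], do_consensus)

    # --- enrichment -------------------------------------------------------
    enr_dir = outdir / "enrich"
    enrichment_tsv = enr_dir / "enrichment.tsv"

    def do_enrich():
        enr_dir.mkdir(exist_ok=True)
        candidates = [
            line.strip()
            for line in open(consensus_txt)
            if line.strip()
        ]
        if cfg.annotation is not None:
            annotation = read_annotation(cfg.annotation)
        else:
            # synthetic deterministic annotation over the gene set
            genes = sorted(g.gene_id for g in sio.read_gene_annotation(cfg_genes))
            rng = np.random.default_rng(cfg.seed + 987)
            n_terms = cfg.enrich["n_terms"]
            rows = []
            for g in genes:
                terms = rng.choice(n_terms, size=2, replace=False)
                for t in terms:
                    rows.append(
                        {"gene_id": g, "term_id": f"T{t + 1:02d}",
                         "term_name": f"synthetic term {t + 1}"}
                    )
            annotation = pd.DataFrame(rows)
        if not candidates:
            logger.warning("enrich: empty consensus list; writing empty table")
            pd.DataFrame(columns=["term_id", "term_name", "p_value"]).to_csv(
                enrichment_tsv, sep="\t", index=False
            )
            return {"n_terms_tested": 0}
        df = enrich(candidates, annotation, alpha=cfg.enrich["alpha"])
        df.to_csv(enrichment_tsv, sep="\t", index=False, float_format="%.10g")
        return {"n_terms_tested": len(df),
                "n_significant": int(df["significant"].sum()) if len(df) else 0}

    stage("enrich", [enrichment_tsv], do_enrich)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
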