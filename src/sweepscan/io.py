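"""Genotype data model, VCF/BED/GFF3 I/O and variant/SNP quality filters.

Conventions
-----------
* ``GenotypeMatrix.positions`` are 1-based physical coordinates, strictly
  increasing within a chromosome (VCF convention).
* Genotypes are coded per sample x site as the number of alternate alleles
  ``{0, 1, 2}``; missing calls are ``-1`` (:data:`MISSING`).
* All region/interval types elsewhere in the package are 0-based half-open;
  BED output is 0-based half-open, TSV output is 1-based inclusive.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Genotype code for a missing diploid call.
MISSING = -1


class VcfFormatError(ValueError):
    """Raised when a VCF violates a structural requirement (e.g. no GT)."""


class InputError(ValueError):
    """Raised for malformed or inconsistent user input."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for one chromosome.

    Parameters
    ----------
    chrom
        Chromosome identifier.
    positions
        1-based physical coordinates (bp), strictly increasing.
    sample_ids
        Ordered, unique sample identifiers; row ``i`` of ``genotypes``
        belongs to ``sample_ids[i]``.
    genotypes
        ``int8`` array of shape ``(n_samples, n_sites)`` with codes in
        ``{0, 1, 2, MISSING}`` counting alternate alleles.
    qd, mq, fs, depth
        Optional per-site INFO annotations (Quality-by-Depth, mapping
        quality, Fisher strand, mean depth across samples). ``NaN`` marks
        a site where the field was absent.
    """

    chrom: str
    positions: np.ndarray
    sample_ids: list[str]
    genotypes: np.ndarray
    qd: np.ndarray | None = None
    mq: np.ndarray | None = None
    fs: np.ndarray | None = None
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise InputError("genotypes must be 2-D (samples x sites)")
        if self.genotypes.shape != (len(self.sample_ids), len(self.positions)):
            raise InputError(
                f"genotype shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.positions)} sites"
            )
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            bad = int(np.flatnonzero(np.diff(self.positions) <= 0)[0]) + 1
            raise InputError(
                f"positions not strictly increasing on {self.chrom} at index "
                f"{bad} (position {int(self.positions[bad])})"
            )
        codes = np.unique(self.genotypes)
        if not np.all(np.isin(codes, [MISSING, 0, 1, 2])):
            raise InputError(f"invalid genotype codes: {codes.tolist()}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InputError("sample_ids are not unique")
        for name in ("qd", "mq", "fs", "depth"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.positions.shape:
                    raise InputError(f"{name} length does not match site count")
                setattr(self, name, arr)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given site index/mask."""
        index = np.asarray(index)
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[index],
            sample_ids=list(self.sample_ids),
            genotypes=self.genotypes[:, index],
            qd=None if self.qd is None else self.qd[index],
            mq=None if self.mq is None else self.mq[index],
            fs=None if self.fs is None else self.fs[index],
            depth=None if self.depth is None else self.depth[index],
        )

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        """Return a new matrix restricted to (and ordered by) ``sample_ids``."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise InputError(f"unknown samples: {missing}")
        rows = [lookup[s] for s in sample_ids]
        return replace(
            self, sample_ids=list(sample_ids), genotypes=self.genotypes[rows, :]
        )

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise InputError(f"unknown sample {exc}") from exc


@dataclass
class PopulationMap:
    """Mapping of sample id to group label."""

    assignments: dict[str, str]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignments.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def validate_contrast(self, obj: str, ref: str) -> None:
        """Check that both contrast groups exist, are distinct and non-empty."""
        if obj == ref:
            raise InputError("object and reference groups must differ")
        for g in (obj, ref):
            if not self.samples_in(g):
                raise InputError(f"group {g!r} is empty or unknown")

    @classmethod
    def read(cls, path: str | Path) -> "PopulationMap":
        """Read a headerless two-column TSV ``sample<TAB>group``."""
        assignments: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise InputError(f"{path}:{lineno}: expected sample<TAB>group")
                sample, group = parts[0], parts[1]
                if sample in assignments:
                    raise InputError(f"{path}:{lineno}: duplicate sample {sample}")
                assignments[sample] = group
        return cls(assignments)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sample, group in self.assignments.items():
                fh.write(f"{sample}\t{group}\n")


@dataclass(frozen=True)
class GeneModel:
    """One gene interval, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError(f"gene {self.gene_id}: start must be < end")


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------


@dataclass
class VcfReadResult:
    """Per-chromosome genotype matrices plus skip counters."""

    matrices: dict[str, GenotypeMatrix]
    sample_ids: list[str] = field(default_factory=list)
    n_skipped_multiallelic: int = 0
    n_skipped_indel: int = 0

    def __iter__(self):
        return iter(self.matrices.values())


def read_vcf(path: str | Path, region: str | None = None) -> VcfReadResult:
    """Read a multi-sample VCF into per-chromosome genotype matrices.

    Only biallelic SNP records are kept; multi-allelic records and indels
    are skipped and counted. INFO fields QD/MQ/FS and a per-site mean depth
    (INFO DP divided by sample count, falling back to the mean of FORMAT
    DP) are captured where present.

    Parameters
    ----------
    path
        Plain or gzip-compressed VCF 4.x file with a GT FORMAT field.
    region
        Optional chromosome name; records on other chromosomes are ignored.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise VcfFormatError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    n = len(samples)

    per_chrom: dict[str, dict[str, list]] = {}
    n_multi = 0
    n_indel = 0
    last_pos: dict[str, int] = {}
    for var in vcf:
        chrom = var.CHROM
        if region is not None and chrom != region:
            continue
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if var.is_indel or not var.is_snp:
            n_indel += 1
            continue
        if chrom in last_pos and var.POS <= last_pos[chrom]:
            raise InputError(
                f"{path}: unsorted VCF at {chrom}:{var.POS} "
                f"(previous position {last_pos[chrom]})"
            )
        last_pos[chrom] = var.POS
        store = per_chrom.setdefault(
            chrom,
            {"pos": [], "gt": [], "qd": [], "mq": [], "fs": [], "depth": []},
        )
        store["pos"].append(var.POS)
        gts = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2, 3 = unknown
        gts[gts == 3] = MISSING
        store["gt"].append(gts)
        store["qd"].append(_info_float(var, "QD"))
        store["mq"].append(_info_float(var, "MQ"))
        store["fs"].append(_info_float(var, "FS"))
        dp = _info_float(var, "DP")
        if not np.isnan(dp):
            depth = dp / n
        else:
            try:
                fmt_dp = var.format("DP")
            except KeyError:
                fmt_dp = None
            depth = float(np.nanmean(fmt_dp)) if fmt_dp is not None else np.nan
        store["depth"].append(depth)
    vcf.close()

    matrices: dict[str, GenotypeMatrix] = {}
    for chrom, store in per_chrom.items():
        qd = np.array(store["qd"], dtype=float)
        mq = np.array(store["mq"], dtype=float)
        fs = np.array(store["fs"], dtype=float)
        depth = np.array(store["depth"], dtype=float)
        matrices[chrom] = GenotypeMatrix(
            chrom=chrom,
            positions=np.array(store["pos"], dtype=np.int64),
            sample_ids=samples,
            genotypes=np.vstack(store["gt"]).T if store["gt"] else
            np.empty((n, 0), dtype=np.int8),
            qd=None if np.isnan(qd).all() else qd,
            mq=None if np.isnan(mq).all() else mq,
            fs=None if np.isnan(fs).all() else fs,
            depth=None if np.isnan(depth).all() else depth,
        )
    if n_multi or n_indel:
        logger.info(
            "read_vcf(%s): skipped %d multi-allelic and %d indel/non-SNP records",
            path, n_multi, n_indel,
        )
    return VcfReadResult(
        matrices=matrices,
        sample_ids=samples,
        n_skipped_multiallelic=n_multi,
        n_skipped_indel=n_indel,
    )


def _info_float(var, key: str) -> float:
    val = var.INFO.get(key)
    try:
        return float(val) if val is not None else np.nan
    except (TypeError, ValueError):
        return np.nan


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    matrices: dict[str, GenotypeMatrix] | Iterable[GenotypeMatrix],
    path: str | Path,
) -> None:
    """Write genotype matrices as a minimal VCF 4.2 file (gzip if ``.gz``).

    Sites are written with placeholder REF/ALT alleles (A/T); QD/MQ/FS/DP
    INFO fields are emitted when the matrix carries them so the file
    round-trips through :func:`read_vcf` and the quality filters.
    """
    if isinstance(matrices, dict):
        mats = list(matrices.values())
    else:
        mats = list(matrices)
    if not mats:
        raise InputError("no genotype matrices to write")
    samples = mats[0].sample_ids
    for gm in mats:
        if gm.sample_ids != samples:
            raise InputError("all chromosomes must share the same sample set")

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for key, typ, desc in (
            ("QD", "Float", "Quality by depth"),
            ("MQ", "Float", "Mapping quality"),
            ("FS", "Float", "Fisher strand"),
            ("DP", "Integer", "Total depth"),
        ):
            fh.write(
                f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">\n'
            )
        for gm in mats:
            length = int(gm.positions[-1]) if gm.n_sites else 1
            fh.write(f"##contig=<ID={gm.chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
            + "FORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for gm in mats:
            for j in range(gm.n_sites):
                info = _format_info(gm, j)
                gts = "\t".join(_GT_STRING[int(g)] for g in gm.genotypes[:, j])
                fh.write(
                    f"{gm.chrom}\t{int(gm.positions[j])}\t.\tA\tT\t.\tPASS\t"
                    f"{info}\tGT\t{gts}\n"
                )


def _format_info(gm: GenotypeMatrix, j: int) -> str:
    parts = []
    for key, arr in (("QD", gm.qd), ("MQ", gm.mq), ("FS", gm.fs)):
        if arr is not None and not np.isnan(arr[j]):
            parts.append(f"{key}={arr[j]:g}")
    if gm.depth is not None and not np.isnan(gm.depth[j]):
        parts.append(f"DP={round(gm.depth[j] * gm.n_samples)}")
    return ";".join(parts) if parts else "."


# ---------------------------------------------------------------------------
# quality filters
# ---------------------------------------------------------------------------


def variant_quality_mask(
    gm: GenotypeMatrix,
    qd_min: float = 2.0,
    mq_min: float = 20.0,
    fs_max: float = 60.0,
) -> tuple[np.ndarray, dict[str, int]]:
    """Boolean keep-mask for the QD/MQ/FS variant-quality filter.

    A site is removed when QD < ``qd_min``, MQ < ``mq_min`` or
    FS > ``fs_max``; boundary values are kept (thresholds are strict).
    Sites lacking a field pass that sub-filter.
    """
    keep = np.ones(gm.n_sites, dtype=bool)
    reasons: dict[str, int] = {}
    for name, arr, bad in (
        ("qd", gm.qd, lambda a: a < qd_min),
        ("mq", gm.mq, lambda a: a < mq_min),
        ("fs", gm.fs, lambda a: a > fs_max),
    ):
        if arr is None:
            logger.info("variant-quality filter: %s absent, sub-filter skipped", name)
            continue
        with np.errstate(invalid="ignore"):
            violates = bad(arr)
        violates &= ~np.isnan(arr)
        reasons[name] = int(violates.sum())
        keep &= ~violates
    return keep, reasons


def filter_variant_quality(
    gm: GenotypeMatrix,
    qd_min: float = 2.0,
    mq_min: float = 20.0,
    fs_max: float = 60.0,
) -> GenotypeMatrix:
    """Drop sites failing the QD/MQ/FS thresholds (order preserved)."""
    keep, reasons = variant_quality_mask(gm, qd_min, mq_min, fs_max)
    if reasons:
        logger.info("variant-quality filter on %s: removed %s", gm.chrom, reasons)
    return gm.take_sites(keep)


def site_call_rate(gm: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing genotype calls per site."""
    if gm.n_samples == 0:
        return np.zeros(gm.n_sites)
    return (gm.genotypes != MISSING).mean(axis=0)


def site_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency per site, from non-missing alleles only.

    Sites with no calls get MAF 0.
    """
    called = gm.genotypes != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, gm.genotypes, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
    return np.minimum(p, 1.0 - p)


def snp_qc_mask(
    gm: GenotypeMatrix,
    call_rate_min: float = 0.9,
    maf_min: float = 0.05,
    depth_min: float = 3.0,
    depth_max: float = 30.0,
) -> tuple[np.ndarray, dict[str, int]]:
    """Boolean keep-mask for the call-rate / MAF / depth SNP filter.

    Removal is inclusive at the call-rate and MAF boundaries (a site with
    call rate exactly 0.9 or MAF exactly 0.05 is removed), and the depth
    band keeps ``depth_min <= depth <= depth_max``.
    """
    reasons: dict[str, int] = {}
    cr = site_call_rate(gm)
    maf = site_maf(gm)
    bad_cr = cr <= call_rate_min
    bad_maf = maf <= maf_min
    reasons["call_rate"] = int(bad_cr.sum())
    reasons["maf"] = int(bad_maf.sum())
    keep = ~(bad_cr | bad_maf)
    if gm.depth is None:
        logger.warning("SNP-QC on %s: depth absent, depth sub-filter skipped", gm.chrom)
    else:
        with np.errstate(invalid="ignore"):
            bad_depth = (gm.depth < depth_min) | (gm.depth > depth_max)
        bad_depth &= ~np.isnan(gm.depth)
        reasons["depth"] = int(bad_depth.sum())
        keep &= ~bad_depth
    return keep, reasons


def filter_snp_qc(
    gm: GenotypeMatrix,
    call_rate_min: float = 0.9,
    maf_min: float = 0.05,
    depth_min: float = 3.0,
    depth_max: float = 30.0,
) -> GenotypeMatrix:
    """Drop sites failing call-rate, MAF or mean-depth criteria."""
    keep, reasons = snp_qc_mask(gm, call_rate_min, maf_min, depth_min, depth_max)
    logger.info("SNP-QC filter on %s: removed %s", gm.chrom, reasons)
    return gm.take_sites(keep)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def read_gene_annotation(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene intervals from BED (>=4 columns) or GFF3 ``gene`` features.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Duplicate gene ids on the same interval are deduplicated; the same id
    on different intervals is an error.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.name.lower()
        if suffix.endswith((".bed", ".bed.gz")):
            fmt = "BED"
        elif suffix.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
            fmt = "GFF3"
        else:
            raise InputError(f"cannot infer annotation format of {path}")
    fmt = fmt.upper()
    if fmt not in ("BED", "GFF3"):
        raise InputError(f"unknown annotation format {fmt!r}")

    opener = gzip.open if path.name.endswith(".gz") else open
    genes: dict[str, GeneModel] = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if fmt == "BED":
                cols = line.split("\t")
                if len(cols) < 4:
                    raise InputError(f"{path}:{lineno}: BED needs >=4 columns")
                model = GeneModel(
                    gene_id=cols[3],
                    chrom=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    strand=cols[5] if len(cols) > 5 else "?",
                )
            else:
                cols = line.split("\t")
                if len(cols) < 9:
                    raise InputError(f"{path}:{lineno}: GFF3 needs 9 columns")
                if cols[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID") or attrs.get("gene_id")
                if not gene_id:
                    raise InputError(f"{path}:{lineno}: gene lacks ID/gene_id")
                model = GeneModel(
                    gene_id=gene_id,
                    chrom=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in "+-" else "?",
                )
            prev = genes.get(model.gene_id)
            if prev is not None:
                if (prev.chrom, prev.start, prev.end) != (
                    model.chrom, model.start, model.end,
                ):
                    raise InputError(
                        f"{path}: gene id {model.gene_id} on conflicting intervals"
                    )
                continue
            genes[model.gene_id] = model
    return list(genes.values())


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def write_regions_bed(
    regions: Iterable[tuple[str, int, int]], path: str | Path
) -> None:
    """Write ``(chrom, start, end)`` regions as 0-based half-open BED."""
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\n")


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int]]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            regions.append((cols[0], int(cols[1]), int(cols[2])))
    return regions


def write_table_tsv(records, path: str | Path) -> None:
    """Write records as TSV with a header; start/end become 1-based inclusive.

    ``records`` is a pandas DataFrame or an iterable of dicts. Columns named
    ``start``/``end`` are assumed 0-based half-open internally and shifted
    to the 1-based inclusive convention on output.
    """
    import pandas as pd

    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df = df.copy()
    if "start" in df.columns and len(df):
        df["start"] = df["start"].astype(int) + 1
    if "end" in df.columns and len(df):
        df["end"] = df["end"].astype(int)
    if df.empty and not len(df.columns):
        # emit at least a header-only file for empty region lists
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table_tsv(path: str | Path):
    """Read a TSV written by :func:`write_table_tsv` back to internal coords."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "start" in df.columns and len(df):
        df["start"] = df["start"].astype(int) - 1
    return df
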