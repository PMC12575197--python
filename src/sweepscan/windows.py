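"""Sliding-window Weir-Cockerham FST and nucleotide diversity.

Windows are 0-based half-open 50 kb intervals advanced in 25 kb steps by
default. FST uses the Weir & Cockerham (1984) two-population variance
components combined across the SNPs of a window as a ratio of sums
(sum(a) / sum(a+b+c)), matching the common "weighted" windowed estimator.
Per-group diversity is the per-site unbiased heterozygosity
2*p*(1-p)*n/(n-1) summed over segregating sites and divided by the full
window span. The genome-wide tracks are then transformed (Z-score for FST,
log2 ratio for diversity) and joint outlier windows are called either by
top-quantile or by absolute thresholds.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from sweepscan.intervals import merge_intervals
from sweepscan.io import MISSING, GenotypeMatrix, InputError, PopulationMap

logger = logging.getLogger(__name__)

WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_snps", "fst",
    "pi_obj", "pi_ref", "log2_pi_ratio", "z_fst",
]


def sliding_windows(
    chromosome_length: int, size: int = 50_000, step: int = 25_000
) -> list[tuple[int, int]]:
    """0-based half-open windows starting at 0, ``step`` apart.

    The final partial window is included iff it covers at least 1 bp.
    """
    if size <= 0 or step <= 0:
        raise InputError("window size and step must be positive")
    if step > size:
        raise InputError("step must not exceed window size")
    return [
        (start, min(start + size, chromosome_length))
        for start in range(0, chromosome_length, step)
    ]


def _window_slice(gm: GenotypeMatrix, window: tuple[int, int]) -> slice:
    # positions are 1-based; a site is in [start, end) iff start < pos <= end
    start, end = window
    lo = int(np.searchsorted(gm.positions, start + 1, side="left"))
    hi = int(np.searchsorted(gm.positions, end, side="right"))
    return slice(lo, hi)


def wc_fst_components(g1: np.ndarray, g2: np.ndarray):
    """Per-site Weir-Cockerham variance components for two populations.

    Parameters are genotype code arrays of shape (n_individuals, n_sites);
    missing calls are excluded site-wise. Returns ``(a, b, c, usable)``
    where ``usable`` marks sites with genotype data in both groups and
    polymorphic across the pooled sample. Non-usable sites get zero
    components.
    """
    r = 2.0
    comps = []
    for g in (g1, g2):
        called = g != MISSING
        n_i = called.sum(axis=0).astype(float)
        alt = np.where(called, g, 0).sum(axis=0).astype(float)
        het = np.where(called, g == 1, False).sum(axis=0).astype(float)
        comps.append((n_i, alt, het))
    (n1, alt1, het1), (n2, alt2, het2) = comps

    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = alt1 / (2 * n1)
        p2 = alt2 / (2 * n2)
        h1 = het1 / n1
        h2 = het2 / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2

    usable = (n1 > 0) & (n2 > 0) & (nbar > 1) & (pbar > 0) & (pbar < 1)
    zero = ~usable
    for arr in (a, b, c):
        arr[zero] = 0.0
    return a, b, c, usable


def wc_fst_window(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    window: tuple[int, int],
    groups: tuple[str, str] | None = None,
) -> tuple[float, int]:
    """Weir-Cockerham FST over one window, ratio-of-sums across SNPs.

    Returns ``(fst, n_usable_snps)``; ``fst`` is NaN when the component
    denominator is zero (e.g. all sites monomorphic).
    """
    if groups is None:
        all_groups = pm.groups
        if len(all_groups) != 2:
            raise InputError(
                f"population map has {len(all_groups)} groups; "
                "wc_fst_window requires exactly 2 (or pass groups=...)"
            )
        groups = (all_groups[0], all_groups[1])
    idx1 = gm.sample_indices(pm.samples_in(groups[0]))
    idx2 = gm.sample_indices(pm.samples_in(groups[1]))
    sl = _window_slice(gm, window)
    a, b, c, usable = wc_fst_components(
        gm.genotypes[idx1, sl], gm.genotypes[idx2, sl]
    )
    denom = (a + b + c).sum()
    fst = float(a.sum() / denom) if denom != 0 else float("nan")
    return fst, int(usable.sum())


def pi_window(
    gm: GenotypeMatrix,
    samples: Sequence[str],
    window: tuple[int, int],
) -> float:
    """Nucleotide diversity per bp for one group over one window.

    Sum over sites of the unbiased per-site heterozygosity
    ``2*p*(1-p)*n/(n-1)`` (``n`` = non-missing allele count), divided by the
    full window span; positions not in the site panel count as invariant.
    """
    idx = gm.sample_indices(samples)
    sl = _window_slice(gm, window)
    g = gm.genotypes[idx, sl]
    called = g != MISSING
    n = 2 * called.sum(axis=0).astype(float)
    alt = np.where(called, g, 0).sum(axis=0).astype(float)
    ok = n >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(ok, alt / np.maximum(n, 1), 0.0)
        site_het = np.where(ok, 2 * p * (1 - p) * n / np.maximum(n - 1, 1), 0.0)
    span = window[1] - window[0]
    return float(site_het.sum() / span)


def compute_window_stats(
    matrices: dict[str, GenotypeMatrix],
    pm: PopulationMap,
    obj: str,
    ref: str,
    size: int = 50_000,
    step: int = 25_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window FST and per-group diversity across all chromosomes.

    ``chrom_lengths`` defaults to the last SNP position per chromosome.
    The returned frame is untransformed; pass it to :func:`transform_stats`.
    """
    pm.validate_contrast(obj, ref)
    obj_samples = pm.samples_in(obj)
    ref_samples = pm.samples_in(ref)
    rows = []
    for chrom, gm in matrices.items():
        if gm.n_sites == 0:
            continue
        length = (chrom_lengths or {}).get(chrom, int(gm.positions[-1]))
        for window in sliding_windows(length, size, step):
            fst, n_snps = wc_fst_window(gm, pm, window, groups=(obj, ref))
            rows.append(
                {
                    "chrom": chrom,
                    "start": window[0],
                    "end": window[1],
                    "n_snps": n_snps,
                    "fst": fst,
                    "pi_obj": pi_window(gm, obj_samples, window),
                    "pi_ref": pi_window(gm, ref_samples, window),
                }
            )
    df = pd.DataFrame(rows, columns=WINDOW_COLUMNS[:7])
    return df


def transform_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Fill ``z_fst`` (genome-wide Z-score) and ``log2_pi_ratio`` columns.

    The Z-score uses the sample standard deviation (ddof=1) over all
    windows with defined FST. ``log2_pi_ratio = log2(pi_ref / pi_obj)`` is
    NaN when either diversity is zero; such windows are excluded from
    outlier calling downstream.
    """
    df = records.copy()
    defined = df["fst"].notna()
    if defined.sum() < 2:
        raise InputError("need at least 2 windows with defined FST")
    mean = df.loc[defined, "fst"].mean()
    sd = df.loc[defined, "fst"].std(ddof=1)
    if df.loc[defined, "fst"].nunique() == 1 or sd == 0:
        raise InputError("FST values are all identical; Z-score undefined")
    df["z_fst"] = (df["fst"] - mean) / sd
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df["pi_ref"] / df["pi_obj"]
        df["log2_pi_ratio"] = np.where(
            (df["pi_ref"] > 0) & (df["pi_obj"] > 0), np.log2(ratio), np.nan
        )
    n_undef = int(df["log2_pi_ratio"].isna().sum())
    if n_undef:
        logger.info("transform_stats: %d windows with undefined pi ratio", n_undef)
    return df


def call_joint_outliers(
    records: pd.DataFrame,
    mode: str = "quantile",
    z_cut: float | None = None,
    ratio_cut: float | None = None,
    q: float = 0.05,
    direction: str = "high",
) -> tuple[pd.DataFrame, list[tuple[str, int, int]]]:
    """Flag windows extreme in both z(FST) and the log2 diversity ratio.

    ``quantile`` mode flags the top ``q`` fraction of each metric (ties at
    the boundary included); ``absolute`` mode applies strict cuts
    ``z_fst > z_cut`` and ``log2_pi_ratio > ratio_cut`` (or ``<`` when
    ``direction="low"``). Windows with undefined FST or ratio never flag.
    Returns the flagged windows and the merged maximal regions.
    """
    df = records
    eligible = df["fst"].notna() & df["log2_pi_ratio"].notna()
    z = df["z_fst"]
    ratio = df["log2_pi_ratio"]
    if direction not in ("high", "low"):
        raise InputError("direction must be 'high' or 'low'")
    if mode == "quantile":
        if not 0 < q < 1:
            raise InputError("quantile q must be in (0, 1)")
        z_thr = z[eligible].quantile(1 - q)
        r_thr = (
            ratio[eligible].quantile(1 - q)
            if direction == "high"
            else ratio[eligible].quantile(q)
        )
        z_hit = z >= z_thr
        r_hit = ratio >= r_thr if direction == "high" else ratio <= r_thr
    elif mode == "absolute":
        if z_cut is None or ratio_cut is None:
            raise InputError("absolute mode requires z_cut and ratio_cut")
        z_hit = z > z_cut
        r_hit = ratio > ratio_cut if direction == "high" else ratio < ratio_cut
    else:
        raise InputError(f"unknown outlier mode {mode!r}")
    flagged = df[eligible & z_hit & r_hit]
    regions = merge_intervals(
        (row.chrom, int(row.start), int(row.end)) for row in flagged.itertuples()
    ) if len(flagged) else []
    return flagged, regions
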