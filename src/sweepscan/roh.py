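"""Runs of homozygosity and group-level ROH islands.

The caller mimics the PLINK sliding-window scan: a fixed-size window of
consecutive SNPs slides along each chromosome, a window is "homozygous"
when it contains at most ``max_het_per_window`` heterozygous and at most
``max_missing_per_window`` missing calls, and a SNP is in a run when at
least one window covering it is homozygous. Maximal runs are split at
physical gaps, then filtered on SNP count, physical length and SNP
density. Island calling converts per-individual segments into the
fraction of group members whose ROH cover each SNP and takes maximal runs
of consecutive SNPs strictly above an occurrence threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from sweepscan.io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RohParams:
    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    min_snps: int = 50
    min_length: int = 500_000
    max_gap: int = 100_000
    max_bp_per_snp: int = 50_000  # density cap: length / n_snps


#: Named parameter presets. "plink" mirrors the defaults above at
#: whole-genome scale; "test" is scaled for ~2 Mb simulated chromosomes.
PRESETS: dict[str, RohParams] = {
    "plink": RohParams(),
    "test": RohParams(
        window_snps=25,
        max_het_per_window=1,
        max_missing_per_window=2,
        min_snps=50,
        min_length=100_000,
        max_gap=100_000,
        max_bp_per_snp=50_000,
    ),
}


@dataclass(frozen=True)
class RohSegment:
    """One homozygous run: 0-based half-open interval spanning the first
    through last SNP of the run."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RohIsland:
    chrom: str
    start: int
    end: int
    peak_occurrence_pct: float
    mean_occurrence_pct: float
    n_snps: int


def call_roh(
    gm: GenotypeMatrix, sample_id: str, params: RohParams = RohParams()
) -> list[RohSegment]:
    """Call ROH segments for one individual on one chromosome."""
    row = gm.sample_indices([sample_id])[0]
    g = gm.genotypes[row, :]
    m = gm.n_sites
    W = params.window_snps
    if m < W:
        logger.warning(
            "call_roh(%s, %s): %d SNPs < window of %d; chromosome skipped",
            sample_id, gm.chrom, m, W,
        )
        return []

    het = (g == 1).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    het_cum = np.concatenate([[0], np.cumsum(het)])
    mis_cum = np.concatenate([[0], np.cumsum(mis)])
    n_win = m - W + 1
    starts = np.arange(n_win)
    win_ok = (
        (het_cum[starts + W] - het_cum[starts] <= params.max_het_per_window)
        & (mis_cum[starts + W] - mis_cum[starts] <= params.max_missing_per_window)
    )
    # SNP j is covered by windows starting in [j - W + 1, j]; it is in a
    # run iff any such window is homozygous.
    ok_cum = np.concatenate([[0], np.cumsum(win_ok.astype(np.int64))])
    j_idx = np.arange(m)
    lo = np.clip(j_idx - W + 1, 0, n_win - 1)
    hi = np.clip(j_idx, 0, n_win - 1)
    covered = (ok_cum[hi + 1] - ok_cum[lo]) > 0

    segments: list[RohSegment] = []
    pos = gm.positions
    j = 0
    while j < m:
        if not covered[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and covered[k + 1]:
            k += 1
        # split the run at physical gaps
        sub_start = j
        for t in range(j, k):
            if pos[t + 1] - pos[t] > params.max_gap:
                segments.append(_make_segment(gm, sample_id, sub_start, t))
                sub_start = t + 1
        segments.append(_make_segment(gm, sample_id, sub_start, k))
        j = k + 1

    kept = [
        seg
        for seg in segments
        if seg.n_snps >= params.min_snps
        and seg.length >= params.min_length
        and seg.length / seg.n_snps <= params.max_bp_per_snp
    ]
    return kept


def _make_segment(
    gm: GenotypeMatrix, sample_id: str, first: int, last: int
) -> RohSegment:
    return RohSegment(
        sample_id=sample_id,
        chrom=gm.chrom,
        start=int(gm.positions[first]) - 1,
        end=int(gm.positions[last]),
        n_snps=last - first + 1,
    )


def occurrence_track(
    segments: list[RohSegment], gm: GenotypeMatrix, group_samples: list[str]
) -> np.ndarray:
    """Percentage of group individuals with >=1 ROH covering each SNP.

    Multiple overlapping ROH of the same individual count once. Returned
    array is aligned with ``gm.positions``.
    """
    if not group_samples:
        raise ValueError("group must contain at least one sample")
    pos0 = gm.positions - 1  # 0-based coordinates of SNPs
    covered_by: dict[str, np.ndarray] = {}
    for seg in segments:
        if seg.chrom != gm.chrom:
            continue
        mask = covered_by.setdefault(seg.sample_id, np.zeros(gm.n_sites, dtype=bool))
        lo = int(np.searchsorted(pos0, seg.start, side="left"))
        hi = int(np.searchsorted(pos0, seg.end, side="left"))
        mask[lo:hi] = True
    counts = np.zeros(gm.n_sites, dtype=np.int64)
    for sample in group_samples:
        if sample in covered_by:
            counts += covered_by[sample]
    return 100.0 * counts / len(group_samples)


def call_islands(
    gm: GenotypeMatrix, track: np.ndarray, threshold_pct: float = 20.0
) -> list[RohIsland]:
    """Maximal runs of consecutive SNPs with occurrence strictly above the
    threshold; the island interval spans the first to last SNP of the run."""
    above = np.asarray(track) > threshold_pct
    islands: list[RohIsland] = []
    m = gm.n_sites
    j = 0
    while j < m:
        if not above[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and above[k + 1]:
            k += 1
        chunk = track[j : k + 1]
        islands.append(
            RohIsland(
                chrom=gm.chrom,
                start=int(gm.positions[j]) - 1,
                end=int(gm.positions[k]),
                peak_occurrence_pct=float(np.max(chunk)),
                mean_occurrence_pct=float(np.mean(chunk)),
                n_snps=k - j + 1,
            )
        )
        j = k + 1
    return islands


def roh_for_group(
    matrices: dict[str, GenotypeMatrix],
    group_samples: list[str],
    params: RohParams = RohParams(),
    island_threshold_pct: float = 20.0,
):
    """Segments, occurrence tracks and islands for a whole group.

    Returns ``(segments, tracks, islands)`` where ``tracks`` maps
    chromosome to the per-SNP occurrence array.
    """
    segments: list[RohSegment] = []
    for gm in matrices.values():
        for sample in group_samples:
            segments.extend(call_roh(gm, sample, params))
    tracks: dict[str, np.ndarray] = {}
    islands: list[RohIsland] = []
    for chrom, gm in matrices.items():
        track = occurrence_track(
            [s for s in segments if s.chrom == chrom], gm, group_samples
        )
        tracks[chrom] = track
        islands.extend(call_islands(gm, track, island_threshold_pct))
    return segments, tracks, islands
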