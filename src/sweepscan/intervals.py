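"""Small shared interval helpers (0-based half-open throughout)."""

from __future__ import annotations

from typing import Iterable

Region = tuple[str, int, int]


def merge_intervals(regions: Iterable[Region]) -> list[Region]:
    """Merge overlapping or touching intervals per chromosome.

    Output is sorted by (chromosome, start). Intervals that share a
    boundary (``end == start``) are merged into one.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged: list[Region] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """True iff half-open intervals share at least 1 bp."""
    return a_start < b_end and b_start < a_end
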