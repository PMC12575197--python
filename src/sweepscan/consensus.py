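"""Gene mapping of outlier regions and three-method consensus (Venn logic)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from sweepscan.intervals import Region, overlaps
from sweepscan.io import GeneModel

logger = logging.getLogger(__name__)


def regions_to_genes(
    regions: Iterable[Region],
    genes: Sequence[GeneModel],
    flank: int = 0,
) -> dict[str, list[Region]]:
    """Map outlier regions to genes by any-overlap.

    A gene is reported iff its interval, extended by ``flank`` bp on both
    sides, intersects some region by at least 1 bp (half-open semantics).
    Returns ``gene_id -> supporting regions``.
    """
    regions = list(regions)
    region_chroms = {r[0] for r in regions}
    gene_chroms = {g.chrom for g in genes}
    if regions and genes and not (region_chroms & gene_chroms):
        logger.warning(
            "regions_to_genes: no shared chromosome names (regions: %s, genes: %s)",
            sorted(region_chroms), sorted(gene_chroms),
        )
    hits: dict[str, list[Region]] = {}
    for gene in genes:
        g_start = max(0, gene.start - flank)
        g_end = gene.end + flank
        support = [
            r
            for r in regions
            if r[0] == gene.chrom and overlaps(g_start, g_end, r[1], r[2])
        ]
        if support:
            hits[gene.gene_id] = support
    return hits


@dataclass
class CandidateGeneReport:
    """Per-method gene sets with all seven exclusive Venn cells.

    ``cells`` is keyed by sorted '+'-joined method-name combinations
    (e.g. ``"fstpi+roh+xpclr"``); each cell is the exclusive set of genes
    found by exactly that combination of methods.
    """

    sets: dict[str, set[str]]
    cells: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        names = sorted(self.sets)
        if len(names) != 3:
            raise ValueError("consensus requires exactly three named gene sets")
        union = set().union(*self.sets.values())
        cells: dict[str, set[str]] = {}
        for gene in union:
            members = tuple(n for n in names if gene in self.sets[n])
            cells.setdefault("+".join(members), set()).add(gene)
        # ensure all 7 cells exist, even when empty
        from itertools import combinations

        for k in (1, 2, 3):
            for combo in combinations(names, k):
                cells.setdefault("+".join(combo), set())
        self.cells = cells

    @property
    def union(self) -> set[str]:
        return set().union(*self.sets.values())

    @property
    def triple(self) -> list[str]:
        """The consensus candidate list: genes found by all three methods."""
        names = sorted(self.sets)
        return sorted(set.intersection(*(self.sets[n] for n in names)))

    def cell_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.cells.items()}


def consensus(gene_sets: Mapping[str, Iterable[str]]) -> CandidateGeneReport:
    """Build the three-method consensus report from named gene sets."""
    return CandidateGeneReport(sets={k: set(v) for k, v in gene_sets.items()})
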