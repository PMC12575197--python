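"""Hypergeometric over-representation test of a candidate gene set.

Given a candidate gene list and a gene -> term annotation, each term with
at least two annotated genes is tested with the exact hypergeometric upper
tail P[X >= k] (one-sided Fisher), where k candidates of n fall in a term
of K genes among N background genes. The background is the set of all
annotated genes unless overridden. Benjamini-Hochberg adjusted values are
reported alongside the raw p-values.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "term_id", "term_name", "k", "K", "n", "N",
    "gene_ratio", "p_value", "neg_log10_p", "p_adjusted", "genes",
]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a headerless ``gene_id<TAB>term_id<TAB>term_name`` TSV."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["gene_id", "term_id", "term_name"],
        dtype=str,
    )
    if df["term_name"].isna().all():
        df["term_name"] = df["term_id"]
    return df


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def enrich(
    candidates: Iterable[str],
    annotation: pd.DataFrame | str | Path,
    alpha: float = 0.05,
    background: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Test each term for over-representation among the candidates.

    Parameters
    ----------
    candidates
        Candidate gene ids; ids absent from the background are dropped
        (with a logged count).
    annotation
        Gene/term table (or its TSV path) with columns
        ``gene_id, term_id, term_name``.
    alpha
        Significance level recorded in the ``significant`` column
        (raw ``p_value < alpha``).
    background
        Optional explicit background gene universe; defaults to all
        annotated genes. Terms with fewer than 2 background genes are
        skipped.
    """
    if not isinstance(annotation, pd.DataFrame):
        annotation = read_annotation(annotation)
    if background is None:
        bg = set(annotation["gene_id"])
    else:
        bg = set(background)
        annotation = annotation[annotation["gene_id"].isin(bg)]
    cand = set(candidates)
    usable = cand & bg
    dropped = len(cand) - len(usable)
    if dropped:
        logger.info("enrich: dropped %d candidates absent from background", dropped)
    if not usable:
        raise ValueError("no candidate genes overlap the annotation background")

    N = len(bg)
    n = len(usable)
    rows = []
    for (term_id, term_name), sub in annotation.groupby(
        ["term_id", "term_name"], sort=True
    ):
        term_genes = set(sub["gene_id"])
        K = len(term_genes)
        if K < 2:
            continue
        members = sorted(usable & term_genes)
        k = len(members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "gene_ratio": k / n,
                "p_value": p,
                "neg_log10_p": -np.log10(p) if p > 0 else np.inf,
                "genes": "|".join(members),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS + ["significant"])
    df["p_adjusted"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["significant"] = df["p_value"] < alpha
    df = df.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
    return df[RESULT_COLUMNS + ["significant"]]
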