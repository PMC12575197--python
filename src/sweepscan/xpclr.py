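"""Cross-population composite-likelihood-ratio sweep scan.

The scan contrasts an object population against a reference population on
a physical grid of putative sweep positions. At each grid point the nearby
SNPs (within a genetic-distance window, nearest first, capped) contribute
weighted log-likelihood terms under two nested models:

* Neutral: the object-group allele frequency ``p`` around the reference
  frequency ``p1`` follows a truncated-normal drift density with variance
  ``omega * p1 * (1 - p1)``; probability mass falling outside (0, 1) is
  collapsed into atoms at 0 and 1.
* Sweep: a hitchhiking mixture. A lineage escapes the sweep with
  probability ``c = 1 - exp(-r / s)`` (``r`` = genetic distance to the grid
  point, ``s`` = selection strength); escaped lineages keep the neutral
  density, dragged lineages map the neutral variable ``u`` to
  ``1 - c + c*u`` when the swept background carries the derived allele
  (probability ``p1``) and to ``c*u`` otherwise.

Both likelihoods integrate binomial sampling of the observed object-group
allele counts against the frequency distribution. The score at a grid
point is ``2 * (max_s sum_i w_i log L1_i(s) - sum_i w_i log L0_i)``; the
exactly-neutral model (``s = 0`` mapped to ``c = 1``) is always in the
search grid, so scores are non-negative by construction.

Highly correlated SNPs are down-weighted: SNPs are greedily clustered
along position order by genotype r-squared with the cluster head, and each
member of an m-SNP cluster receives weight 1/m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr

from sweepscan.intervals import merge_intervals
from sweepscan.io import MISSING, GenotypeMatrix, InputError, PopulationMap

logger = logging.getLogger(__name__)

POINT_COLUMNS = ["chrom", "position", "score", "s_hat", "n_snps", "eff_n"]


def _default_s_grid() -> np.ndarray:
    # 0.0 denotes the exactly-neutral model (c == 1 at every distance);
    # the remaining 11 values span effectively-neutral to strong sweeps.
    return np.concatenate([[0.0], np.logspace(-5, -0.5, 11)])


@dataclass
class XpclrConfig:
    """Scan parameters; defaults follow the conventional tool invocation
    (0.005 Morgan window, 200-SNP cap, 2 kb grid, r^2 > 0.95 down-weight)."""

    grid_spacing: int = 2_000
    window_genetic_span: float = 0.005  # Morgans, half-width around grid point
    max_snps_per_window: int = 200
    corr_threshold: float = 0.95
    morgans_per_bp: float = 1e-8  # uniform map, 1 cM/Mb
    s_grid: np.ndarray = field(default_factory=_default_s_grid)
    quadrature_points: int = 512
    top_fraction: float = 0.01
    #: optional non-uniform map: chromosome -> (bp positions, cumulative
    #: Morgans), linearly interpolated; overrides ``morgans_per_bp``
    genetic_map: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0 or self.window_genetic_span <= 0:
            raise InputError("grid spacing and genetic span must be positive")
        if not 0 < self.corr_threshold <= 1:
            raise InputError("corr_threshold must be in (0, 1]")
        if self.max_snps_per_window <= 0 or self.quadrature_points <= 0:
            raise InputError("SNP cap and quadrature points must be positive")
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        if not np.any(self.s_grid == 0.0):
            self.s_grid = np.concatenate([[0.0], self.s_grid])


# ---------------------------------------------------------------------------
# neutral drift density
# ---------------------------------------------------------------------------


def neutral_frequency_distribution(
    p1: float, omega: float, q_points: int = 512
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Discretized truncated-normal drift distribution of frequency.

    Returns ``(u, mass, atom0, atom1)``: evaluation points ``u`` at cell
    midpoints of a uniform partition of (0, 1), the exact normal
    probability mass of each cell, and the boundary atoms absorbing the
    mass below 0 and above 1. The masses and atoms sum to 1 by
    construction.
    """
    sigma = np.sqrt(max(omega, 0.0) * p1 * (1.0 - p1))
    edges = np.linspace(0.0, 1.0, q_points + 1)
    u = 0.5 * (edges[:-1] + edges[1:])
    if sigma == 0.0:
        mass = np.zeros(q_points)
        mass[np.searchsorted(edges, p1, side="right") - 1] = 1.0
        return u, mass, 0.0, 0.0
    cdf = ndtr((edges - p1) / sigma)
    mass = np.diff(cdf)
    atom0 = float(cdf[0])
    atom1 = float(1.0 - cdf[-1])
    return u, mass, atom0, atom1


# ---------------------------------------------------------------------------
# drift variance estimation
# ---------------------------------------------------------------------------


def _group_freqs(gm: GenotypeMatrix, samples) -> tuple[np.ndarray, np.ndarray]:
    idx = gm.sample_indices(samples)
    g = gm.genotypes[idx, :]
    called = g != MISSING
    n = 2 * called.sum(axis=0).astype(float)
    alt = np.where(called, g, 0).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n


def estimate_omega(
    matrices: dict[str, GenotypeMatrix] | GenotypeMatrix,
    pm: PopulationMap,
    obj: str,
    ref: str,
) -> float:
    """Method-of-moments drift variance over all usable sites.

    ``omega = mean[(p2 - p1)^2 / (p1 (1 - p1))]`` across sites where the
    reference frequency ``p1`` is strictly inside (0, 1) and both groups
    have calls.
    """
    if isinstance(matrices, GenotypeMatrix):
        matrices = {matrices.chrom: matrices}
    num: list[np.ndarray] = []
    for gm in matrices.values():
        p1, n1 = _group_freqs(gm, pm.samples_in(ref))
        p2, n2 = _group_freqs(gm, pm.samples_in(obj))
        ok = (n1 > 0) & (n2 > 0) & (p1 > 0) & (p1 < 1) & ~np.isnan(p2)
        if ok.any():
            num.append((p2[ok] - p1[ok]) ** 2 / (p1[ok] * (1 - p1[ok])))
    if not num:
        raise InputError("no usable polymorphic sites for omega estimation")
    vals = np.concatenate(num)
    if len(vals) < 100:
        logger.warning("estimate_omega: only %d usable sites (<100)", len(vals))
    return float(vals.mean())


# ---------------------------------------------------------------------------
# SNP weights
# ---------------------------------------------------------------------------


def snp_weights(genotypes: np.ndarray, corr_threshold: float = 0.95) -> np.ndarray:
    """Down-weight correlated SNPs by greedy position-ordered clustering.

    ``genotypes`` has shape (n_samples, n_snps) in position order. A SNP
    joins the current cluster iff its genotype r^2 with the cluster's first
    SNP exceeds ``corr_threshold``; every member of an m-SNP cluster gets
    weight 1/m. Pairs with missing calls are dropped from the correlation;
    an undefined r^2 (constant genotypes, <2 shared calls) never joins.
    """
    m = genotypes.shape[1]
    if m == 0:
        return np.zeros(0)
    weights = np.empty(m)
    head = 0
    cluster = [0]
    for j in range(1, m + 1):
        join = False
        if j < m:
            r2 = _pairwise_r2(genotypes[:, head], genotypes[:, j])
            join = r2 > corr_threshold
        if join:
            cluster.append(j)
        else:
            weights[cluster] = 1.0 / len(cluster)
            if j < m:
                head = j
                cluster = [j]
    return weights


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


# ---------------------------------------------------------------------------
# site panel preparation
# ---------------------------------------------------------------------------


@dataclass
class _SitePanel:
    """Per-chromosome arrays reused across grid points."""

    chrom: str
    positions: np.ndarray  # 1-based bp
    genetic_pos: np.ndarray  # cumulative Morgans
    k: np.ndarray  # object-group alternate allele counts
    n: np.ndarray  # object-group non-missing allele counts
    p1: np.ndarray  # clamped reference frequencies
    obj_genotypes: np.ndarray  # (n_obj_samples, n_sites) for r^2
    u: np.ndarray  # shared quadrature points
    mass: np.ndarray  # (n_sites, Q) neutral cell masses
    atom0: np.ndarray
    atom1: np.ndarray
    log_l0: np.ndarray  # per-site neutral log-likelihood
    log_choose: np.ndarray  # log C(n, k) per site


def prepare_panel(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    obj: str,
    ref: str,
    config: XpclrConfig,
    omega: float,
) -> _SitePanel:
    """Precompute per-site quantities for scanning one chromosome.

    Sites monomorphic across the pooled sample are dropped (they carry no
    contrast information); reference frequencies are clamped away from 0
    and 1 so the neutral density never degenerates.
    """
    pm.validate_contrast(obj, ref)
    p1_raw, n1 = _group_freqs(gm, pm.samples_in(ref))
    idx_obj = gm.sample_indices(pm.samples_in(obj))
    g_obj = gm.genotypes[idx_obj, :]
    called = g_obj != MISSING
    n = 2 * called.sum(axis=0).astype(float)
    k = np.where(called, g_obj, 0).sum(axis=0).astype(float)

    with np.errstate(invalid="ignore"):
        pooled = (k + np.nan_to_num(p1_raw) * n1 * 2) / np.maximum(n + 2 * n1, 1)
    keep = (n > 0) & (n1 > 0) & (pooled > 0) & (pooled < 1)
    positions = gm.positions[keep]
    k = k[keep]
    n = n[keep]
    p1 = p1_raw[keep]
    clamp = 1.0 / (2 * n1[keep] + 2)
    p1 = np.clip(p1, clamp, 1.0 - clamp)

    Q = config.quadrature_points
    m = len(positions)
    u = 0.5 * (np.linspace(0, 1, Q + 1)[:-1] + np.linspace(0, 1, Q + 1)[1:])
    mass = np.empty((m, Q))
    atom0 = np.empty(m)
    atom1 = np.empty(m)
    for i in range(m):
        _, mass[i], atom0[i], atom1[i] = neutral_frequency_distribution(
            p1[i], omega, Q
        )
    log_choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    pmf_grid = _binom_pmf(k[:, None], n[:, None], log_choose[:, None], u[None, :])
    l0 = (mass * pmf_grid).sum(axis=1)
    l0 += atom0 * (k == 0) + atom1 * (k == n)
    with np.errstate(divide="ignore"):
        log_l0 = np.log(l0)
    return _SitePanel(
        chrom=gm.chrom,
        positions=positions,
        genetic_pos=genetic_position(positions, gm.chrom, config),
        k=k,
        n=n,
        p1=p1,
        obj_genotypes=g_obj[:, keep],
        u=u,
        mass=mass,
        atom0=atom0,
        atom1=atom1,
        log_l0=log_l0,
        log_choose=log_choose,
    )


def _binom_pmf(k, n, log_choose, p):
    """Binomial pmf, broadcasting; exact at p = 0 and p = 1."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logpmf = log_choose + k * np.log(p) + (n - k) * np.log1p(-p)
    pmf = np.exp(logpmf)
    pmf = np.where((p == 0.0) & np.broadcast_to(k == 0, pmf.shape), 1.0, pmf)
    pmf = np.where((p == 0.0) & np.broadcast_to(k > 0, pmf.shape), 0.0, pmf)
    pmf = np.where((p == 1.0) & np.broadcast_to(k == n, pmf.shape), 1.0, pmf)
    pmf = np.where((p == 1.0) & np.broadcast_to(k < n, pmf.shape), 0.0, pmf)
    return pmf


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def genetic_position(
    positions: np.ndarray, chrom: str, config: XpclrConfig
) -> np.ndarray:
    """Cumulative genetic position (Morgans) of physical coordinates.

    Uses the supplied non-uniform map for the chromosome when present
    (linear interpolation, constant extrapolation at the map ends),
    otherwise the uniform ``morgans_per_bp`` rate.
    """
    if config.genetic_map and chrom in config.genetic_map:
        bp, morgans = config.genetic_map[chrom]
        return np.interp(positions, bp, morgans)
    return np.asarray(positions, dtype=float) * config.morgans_per_bp


def read_genetic_map(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a map TSV ``chromosome<TAB>position<TAB>cumulative_morgans``."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "position", "morgans"], comment="#")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("position")
        out[str(chrom)] = (
            sub["position"].to_numpy(dtype=float),
            sub["morgans"].to_numpy(dtype=float),
        )
    return out


def _select_window(panel: _SitePanel, grid_position: int, config: XpclrConfig):
    """Indices of panel SNPs within the genetic window, nearest first,
    capped at the SNP limit. The capped nearest-first set is a contiguous
    block in position order."""
    grid_g = genetic_position(np.array([grid_position]), panel.chrom, config)[0]
    r = np.abs(panel.genetic_pos - grid_g)
    dist_bp = np.abs(panel.positions - grid_position)
    in_span = np.flatnonzero(r <= config.window_genetic_span)
    if len(in_span) > config.max_snps_per_window:
        order = in_span[np.argsort(dist_bp[in_span], kind="stable")]
        in_span = np.sort(order[: config.max_snps_per_window])
    return in_span, r[in_span]


def _score_window(
    panel: _SitePanel,
    r: np.ndarray,
    idx: np.ndarray,
    weights: np.ndarray,
    config: XpclrConfig,
) -> tuple[float, float]:
    """Composite score and argmax selection strength for one window."""
    k = panel.k[idx][:, None]
    n = panel.n[idx][:, None]
    log_choose = panel.log_choose[idx][:, None]
    mass = panel.mass[idx]
    atom0 = panel.atom0[idx]
    atom1 = panel.atom1[idx]
    p1 = panel.p1[idx]
    log_l0 = panel.log_l0[idx]
    u = panel.u[None, :]
    neutral_total = float((weights * log_l0).sum())

    best = neutral_total
    s_hat = 0.0
    for s in config.s_grid:
        if s == 0.0:
            total = neutral_total
        else:
            c = 1.0 - np.exp(-r / s)
            cc = c[:, None]
            # dragged branch, swept background carries the derived allele
            pmf1 = _binom_pmf(k, n, log_choose, 1.0 - cc + cc * u)
            i1 = (mass * pmf1).sum(axis=1)
            i1 += atom0 * _binom_pmf(k[:, 0], n[:, 0], log_choose[:, 0], 1.0 - c)
            i1 += atom1 * (k[:, 0] == n[:, 0])
            # dragged branch, swept background carries the ancestral allele
            pmf2 = _binom_pmf(k, n, log_choose, cc * u)
            i2 = (mass * pmf2).sum(axis=1)
            i2 += atom0 * (k[:, 0] == 0)
            i2 += atom1 * _binom_pmf(k[:, 0], n[:, 0], log_choose[:, 0], c)
            l1 = c * np.exp(log_l0) + (1.0 - c) * (p1 * i1 + (1.0 - p1) * i2)
            with np.errstate(divide="ignore"):
                total = float((weights * np.log(l1)).sum())
        if total > best:
            best = total
            s_hat = float(s)
    return 2.0 * (best - neutral_total), s_hat


def xpclr_point(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    grid_position: int,
    config: XpclrConfig,
    omega: float,
    obj: str = "fat",
    ref: str = "thin",
    panel: _SitePanel | None = None,
) -> dict:
    """Score a single grid position; see module docstring for the model.

    A window with no SNPs yields ``score = NaN`` and ``n_snps = 0``.
    """
    if panel is None:
        panel = prepare_panel(gm, pm, obj, ref, config, omega)
    idx, r = _select_window(panel, grid_position, config)
    if len(idx) == 0:
        return {
            "chrom": panel.chrom, "position": grid_position,
            "score": float("nan"), "s_hat": float("nan"),
            "n_snps": 0, "eff_n": 0.0,
        }
    weights = snp_weights(panel.obj_genotypes[:, idx], config.corr_threshold)
    score, s_hat = _score_window(panel, r, idx, weights, config)
    return {
        "chrom": panel.chrom, "position": int(grid_position),
        "score": score, "s_hat": s_hat,
        "n_snps": int(len(idx)), "eff_n": float(weights.sum()),
    }


def xpclr_scan(
    matrices: dict[str, GenotypeMatrix],
    pm: PopulationMap,
    config: XpclrConfig,
    obj: str = "fat",
    ref: str = "thin",
    omega: float | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, int, int]]]:
    """Score every grid point genome-wide and flag the top-fraction regions.

    Points whose score exceeds the genome-wide ``1 - top_fraction``
    quantile are flagged; flagged points no more than one grid step apart
    are merged, and each merged run becomes a region extended by half a
    grid step on both flanks (so a lone point still spans one grid cell).
    """
    if omega is None:
        omega = estimate_omega(matrices, pm, obj, ref)
    frames = []
    for chrom, gm in matrices.items():
        panel = prepare_panel(gm, pm, obj, ref, config, omega)
        length = (chrom_lengths or {}).get(chrom, int(gm.positions[-1]) if gm.n_sites else 0)
        rows = []
        for pos in range(0, length + 1, config.grid_spacing):
            rows.append(
                xpclr_point(gm, pm, pos, config, omega, obj, ref, panel=panel)
            )
        frames.append(pd.DataFrame(rows, columns=POINT_COLUMNS))
    points = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=POINT_COLUMNS
    )
    scored = points["score"].dropna()
    if scored.empty:
        return points, []
    threshold = scored.quantile(1.0 - config.top_fraction)
    flagged = points[points["score"] >= threshold]
    half = config.grid_spacing // 2
    regions = merge_intervals(
        (
            row.chrom,
            max(0, int(row.position) - half),
            int(row.position) + max(half, 1),
        )
        for row in flagged.itertuples()
    )
    return points, regions
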