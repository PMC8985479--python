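"""Conditional Q-Q curves and conditional/conjunctional FDR estimation.

Given harmonized p-values (p1, p2) for two traits, the conditional FDR of a
variant for trait 1 given trait 2 is estimated with the conservative
(null-proportion π0 = 1) empirical-Bayes construction

    cFDR(p1 | p2 <= c) = min(1, p1 / F̂(p1 | p2 <= c)),

where F̂ is the LD-weighted empirical cdf of trait-1 p-values restricted to
the stratum of SNPs whose trait-2 p-value is at most the conditioning cut c.
The conjunctional FDR is the maximum of the two conditional FDRs with the
trait roles swapped; it upper-bounds the FDR for association with both
traits simultaneously.

Grid construction and monotonization
------------------------------------
cFDR values are tabulated on a grid of p1 nodes × p2 cuts and queried by
bilinear interpolation in (log10 p1, log10 p2) of log10 cFDR.  Within a
conditioning stratum the raw per-data-point values p_(i)/F̂(p_(i)) need not
be monotone in p1; they are monotonized by a running maximum along
increasing p1 over the stratum's data points (conservative: dips below an
earlier estimate are raised).  A grid node takes the monotonized value of
the first data point at or above it, which makes grid values at data points
identical to direct counting whenever the data-point sequence is already
monotone.  Below the smallest data point, where the ecdf has no support,
the estimate is extrapolated linearly through the first ecdf jump.  Across
conditioning cuts a running minimum toward stricter cuts enforces that
tightening the conditioning never raises the estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .ld import PruningWeights
from .sumstats import P_FLOOR

logger = logging.getLogger(__name__)

LOG10_E = float(np.log10(np.e))  # mean of -log10 U(0,1)

DEFAULT_QQ_THRESHOLDS = (1.0, 0.1, 0.01, 0.001)

CONJ_COLUMNS = [
    "snp_id", "chrom", "pos", "p1", "p2",
    "cfdr_1given2", "cfdr_2given1", "conjfdr",
]


class WeightedECDF:
    """Right-continuous weighted empirical cdf F̂(x) = Σ w·1[v <= x] / Σ w."""

    def __init__(self, values, weights=None):
        v = np.asarray(values, dtype=float)
        w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
        if v.shape != w.shape:
            raise InputError("values and weights length mismatch")
        if np.any(w < 0):
            raise InputError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise InputError("total weight is zero")
        order = np.argsort(v, kind="mergesort")
        self.values = v[order]
        self.cumw = np.cumsum(w[order])
        self.total = float(total)

    def __call__(self, x):
        idx = np.searchsorted(self.values, np.asarray(x, dtype=float), side="right")
        out = np.where(idx > 0, self.cumw[np.maximum(idx - 1, 0)], 0.0) / self.total
        return out if np.ndim(x) else float(out)


def weighted_ecdf(values, weights=None) -> WeightedECDF:
    """Build a :class:`WeightedECDF` step function."""
    return WeightedECDF(values, weights)


# -- conditional Q-Q -------------------------------------------------------


@dataclass
class QQCurve:
    """One stratum of a conditional Q-Q plot, on the -log10 p scale.

    ``expected`` are weighted plotting positions of the standard uniform
    (Hazen positions, -log10[(cumw - w/2)/W]), ``observed`` the matching
    stratum quantiles of the primary trait's p-values; both are sorted by
    increasing expected value.
    """

    stratum_threshold: float
    expected: np.ndarray
    observed: np.ndarray
    point_weights: np.ndarray
    effective_n: float  # total weight in the stratum

    @property
    def kish_n(self) -> float:
        """Effective number of independent points, (Σw)²/Σw²."""
        w = self.point_weights
        return float(w.sum() ** 2 / np.square(w).sum())


def conditional_qq(
    pair: pd.DataFrame,
    weights: PruningWeights | None = None,
    thresholds=DEFAULT_QQ_THRESHOLDS,
    min_stratum_weight: float = 50.0,
) -> list[QQCurve]:
    """Q-Q curves of p1 within strata of increasingly significant p2.

    The stratum at threshold 1 contains all SNPs; other strata take SNPs
    with p2 < threshold.  Strata whose total weight falls below
    ``min_stratum_weight`` are omitted with a warning.
    """
    if pair.empty:
        raise InputError("empty harmonized pair")
    thresholds = sorted(set(float(t) for t in thresholds), reverse=True)
    p1 = pair["p1"].to_numpy(dtype=float)
    p2 = pair["p2"].to_numpy(dtype=float)
    w_all = (
        np.ones(len(pair))
        if weights is None
        else weights.for_snps(pair["snp_id"])
    )
    curves = []
    for thr in thresholds:
        mask = np.ones(len(pair), dtype=bool) if thr >= 1.0 else p2 < thr
        w = w_all[mask]
        total = w.sum()
        if total < min_stratum_weight:
            logger.warning(
                "conditional_qq: stratum p2 < %g has total weight %.1f < %.1f; omitted",
                thr, total, min_stratum_weight,
            )
            continue
        ps = np.clip(p1[mask], P_FLOOR, 1.0)
        order = np.argsort(ps, kind="mergesort")
        ps, ws = ps[order], w[order]
        frac = (np.cumsum(ws) - 0.5 * ws) / total
        expected = -np.log10(frac)
        observed = -np.log10(ps)
        curves.append(
            QQCurve(
                stratum_threshold=thr,
                expected=expected[::-1].copy(),
                observed=observed[::-1].copy(),
                point_weights=ws[::-1].copy(),
                effective_n=float(total),
            )
        )
    return curves


def qq_deflection(curve: QQCurve) -> float:
    """Mean leftward deflection of a Q-Q curve from the null diagonal.

    Weighted mean of observed -log10 p minus its null expectation
    log10(e) ≈ 0.4343.  Zero in expectation for uniform p-values; positive
    under enrichment.
    """
    w = curve.point_weights
    return float((curve.observed * w).sum() / w.sum() - LOG10_E)


def qq_deflection_band(effective_n: float, alpha: float = 0.05) -> float:
    """Half-width of the null band for :func:`qq_deflection`.

    Under the null, -log10 p are iid Exponential with mean and standard
    deviation log10(e); the mean over n effective points is approximately
    normal, giving a two-sided band of z_{1-α/2}·log10(e)/sqrt(n).
    """
    z = stats.norm.isf(alpha / 2.0)
    return float(z * LOG10_E / np.sqrt(effective_n))


def qq_pointwise_band(n: int, frac, alpha: float = 0.05):
    """Pointwise null band for an (unweighted) Q-Q curve.

    For plotting position fraction ``frac`` among ``n`` uniforms, the
    corresponding order statistic is Beta(k, n+1-k) with k = ceil(frac·n);
    returns (-log10 upper, -log10 lower) observed bounds.
    """
    f = np.asarray(frac, dtype=float)
    k = np.clip(np.ceil(f * n), 1, n)
    lo = stats.beta.ppf(alpha / 2.0, k, n + 1 - k)
    hi = stats.beta.ppf(1 - alpha / 2.0, k, n + 1 - k)
    return -np.log10(hi), -np.log10(lo)


def curves_to_frame(curves: list[QQCurve]) -> pd.DataFrame:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "stratum": c.stratum_threshold,
                    "expected": c.expected,
                    "observed": c.observed,
                    "weight": c.point_weights,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# -- condFDR grid ----------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Node layout for the cFDR lookup grid.

    p1 nodes are log-spaced and, by default, augmented with the observed
    primary p-values so that evaluation at data points is exact.  p2 cuts
    are log-spaced and augmented with the observed conditional p-values
    when there are at most ``max_data_cuts`` distinct values (small inputs),
    again for exactness; larger inputs rely on log-bilinear interpolation.
    """

    p1_min: float = 1e-12
    n_p1: int = 200
    p2_min: float = 1e-8
    n_p2: int = 40
    augment_p1: bool = True
    max_data_cuts: int = 256


@dataclass
class CondFdrGrid:
    """2D lookup of cFDR(primary p | conditional p <= cut)."""

    log10_p1: np.ndarray  # ascending node positions
    log10_p2: np.ndarray  # ascending cut positions
    values: np.ndarray    # shape (n_p1, n_p2), in (0, 1]
    orientation: str      # e.g. "1|2": trait 1 conditioned on trait 2


def _stratum_column(p1_nodes: np.ndarray, p_sorted: np.ndarray,
                    cumw: np.ndarray, total: float) -> np.ndarray:
    """cFDR at p1 nodes for one conditioning stratum (sorted p1 + cum weights).

    The per-data-point estimates p_(i)/F̂(p_(i)) are monotonized by a running
    maximum along increasing p1 *at the data points* (conservative: a raw dip
    below an earlier estimate is raised, never the reverse), and a node takes
    the value of the first data point at or above it.  Anchoring the running
    max at data points rather than dense nodes keeps node values at the data
    exactly equal to direct counting whenever the raw sequence is monotone.
    """
    c_data = np.minimum(1.0, p_sorted * total / cumw)
    c_star = np.maximum.accumulate(c_data)
    idx = np.searchsorted(p_sorted, p1_nodes, side="left")
    col = np.empty(len(p1_nodes))
    inside = idx < len(p_sorted)
    col[inside] = c_star[idx[inside]]
    # above the largest data point the ecdf is 1, so raw cFDR = p1
    col[~inside] = np.maximum(c_star[-1], np.minimum(1.0, p1_nodes[~inside]))
    # below the smallest data point, extrapolate through the first jump
    below = p1_nodes < p_sorted[0]
    if below.any():
        slope = total / cumw[0]
        col[below] = np.minimum(c_star[0], p1_nodes[below] * slope)
    return np.clip(col, P_FLOOR, 1.0)


def build_condfdr_grid(
    pair: pd.DataFrame,
    weights: PruningWeights | None = None,
    grid: GridSpec | None = None,
    orientation: str = "1|2",
) -> CondFdrGrid:
    """Tabulate cFDR(primary | conditional <= cut) over a p1 × p2-cut grid.

    ``orientation`` "1|2" treats p1 as primary and conditions on p2;
    "2|1" swaps the roles.  Conditioning strata that contain no SNPs are
    filled from the nearest populated (looser) cut, logged.
    """
    if grid is None:
        grid = GridSpec()
    if orientation not in ("1|2", "2|1"):
        raise InputError(f"unknown orientation {orientation!r}")
    if len(pair) < 1000:
        logger.warning(
            "build_condfdr_grid: only %d SNPs; cFDR estimates will be coarse", len(pair)
        )
    prim = pair["p1" if orientation == "1|2" else "p2"].to_numpy(dtype=float)
    cond = pair["p2" if orientation == "1|2" else "p1"].to_numpy(dtype=float)
    prim = np.clip(prim, P_FLOOR, 1.0)
    cond = np.clip(cond, P_FLOOR, 1.0)
    w = np.ones(len(pair)) if weights is None else weights.for_snps(pair["snp_id"])

    p1_nodes = np.logspace(np.log10(grid.p1_min), 0.0, grid.n_p1)
    if grid.augment_p1:
        p1_nodes = np.union1d(p1_nodes, np.clip(prim, grid.p1_min, 1.0))
    cuts = np.logspace(np.log10(grid.p2_min), 0.0, grid.n_p2)
    uniq_cond = np.unique(cond)
    if len(uniq_cond) <= grid.max_data_cuts:
        cuts = np.union1d(cuts, np.clip(uniq_cond, grid.p2_min, 1.0))

    order = np.argsort(cond, kind="mergesort")
    prim_by_cond, w_by_cond, cond_sorted = prim[order], w[order], cond[order]

    values = np.empty((len(p1_nodes), len(cuts)))
    empty_cols = []
    for j, c in enumerate(cuts):
        m = int(np.searchsorted(cond_sorted, c, side="right"))
        if m == 0 or w_by_cond[:m].sum() <= 0:
            empty_cols.append(j)
            continue
        ps = prim_by_cond[:m]
        ws = w_by_cond[:m]
        o = np.argsort(ps, kind="mergesort")
        ps, ws = ps[o], ws[o]
        cumw = np.cumsum(ws)
        values[:, j] = _stratum_column(p1_nodes, ps, cumw, float(cumw[-1]))
    if empty_cols:
        logger.info(
            "build_condfdr_grid: %d empty conditioning cuts filled from nearest populated cut",
            len(empty_cols),
        )
        populated = [j for j in range(len(cuts)) if j not in set(empty_cols)]
        if not populated:
            raise InputError("every conditioning stratum is empty")
        for j in empty_cols:
            nearest = min(populated, key=lambda k: (abs(k - j), -k))
            values[:, j] = values[:, nearest]

    # stricter conditioning never raises the estimate
    values = np.minimum.accumulate(values[:, ::-1], axis=1)[:, ::-1]
    values = np.clip(values, P_FLOOR, 1.0)
    return CondFdrGrid(
        log10_p1=np.log10(p1_nodes),
        log10_p2=np.log10(cuts),
        values=values,
        orientation=orientation,
    )


def _interp_axis(nodes: np.ndarray, x: np.ndarray):
    """Clamped linear-interpolation indices/weights along one axis."""
    x = np.clip(x, nodes[0], nodes[-1])
    hi = np.clip(np.searchsorted(nodes, x, side="left"), 1, len(nodes) - 1)
    lo = hi - 1
    span = nodes[hi] - nodes[lo]
    t = np.where(span > 0, (x - nodes[lo]) / np.where(span > 0, span, 1.0), 0.0)
    return lo, hi, t


def lookup_condfdr(grid: CondFdrGrid, p1, p2):
    """Evaluate the grid at (p1, p2) by bilinear interpolation of
    log10 cFDR in (log10 p1, log10 p2); queries outside the grid clamp to
    the boundary.  ``p1`` here is the grid's primary axis."""
    scalar = np.ndim(p1) == 0 and np.ndim(p2) == 0
    x = np.log10(np.clip(np.atleast_1d(np.asarray(p1, dtype=float)), P_FLOOR, 1.0))
    y = np.log10(np.clip(np.atleast_1d(np.asarray(p2, dtype=float)), P_FLOOR, 1.0))
    if x.shape != y.shape:
        raise InputError("p1 and p2 shapes differ")
    lv = np.log10(grid.values)
    ilo, ihi, tx = _interp_axis(grid.log10_p1, x)
    jlo, jhi, ty = _interp_axis(grid.log10_p2, y)
    v = (
        lv[ilo, jlo] * (1 - tx) * (1 - ty)
        + lv[ihi, jlo] * tx * (1 - ty)
        + lv[ilo, jhi] * (1 - tx) * ty
        + lv[ihi, jhi] * tx * ty
    )
    out = np.clip(10.0 ** v, P_FLOOR, 1.0)
    return float(out[0]) if scalar else out


def compute_conjfdr(
    pair: pd.DataFrame,
    weights: PruningWeights | None = None,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """Per-SNP condFDR in both orientations and their maximum (conjFDR).

    Builds both grid orientations, evaluates each SNP at its own (p1, p2),
    and sets conjfdr = max(cfdr_1given2, cfdr_2given1).  Deterministic for
    fixed inputs.
    """
    g12 = build_condfdr_grid(pair, weights, grid, orientation="1|2")
    g21 = build_condfdr_grid(pair, weights, grid, orientation="2|1")
    p1 = pair["p1"].to_numpy(dtype=float)
    p2 = pair["p2"].to_numpy(dtype=float)
    c12 = lookup_condfdr(g12, p1, p2)
    c21 = lookup_condfdr(g21, p2, p1)
    out = pd.DataFrame(
        {
            "snp_id": pair["snp_id"].to_numpy(),
            "chrom": pair["chrom"].to_numpy(),
            "pos": pair["pos"].to_numpy(),
            "p1": p1,
            "p2": p2,
            "cfdr_1given2": c12,
            "cfdr_2given1": c21,
            "conjfdr": np.maximum(c12, c21),
        }
    )
    return out
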