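"""Age-trajectory modelling: linear models, LOESS curves, DE-SWAN.

Three complementary views of how features move with age:

* **Linear** — per-feature ordinary least squares of log10 abundance on
  age with sex as a covariate (``y ~ a + b1*age + b2*sex``); the age term
  is tested with a Type-II F test (equivalent, in this additive model, to
  the squared t of the age coefficient), BH-adjusted across features.
* **Nonlinear** — LOESS (locally weighted polynomial regression, tricube
  weights, degree 2 by default) evaluated on an age grid, z-standardized
  and hierarchically clustered into k trajectory archetypes.
* **Transient** — DE-SWAN: for each center age c, samples inside a
  window are split into a young stratum [c - w/2, c) and an old stratum
  (c, c + w/2] (samples at exactly c excluded), each feature is tested
  via a linear model on the stratum indicator plus sex, and the count of
  significant features per center traces a curve whose local maxima mark
  ages of concentrated metabolic change.

Because the LOESS fitted value at a grid point is linear in the
responses, the smoother is computed once per grid point from the ages
alone and applied to every feature as a matrix product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .core_tables import (
    FeatureTable,
    FeatureTableError,
    SampleMeta,
    log_transform,
)
from .differential import bh_adjust

__all__ = [
    "fit_linear_age",
    "LoessResult",
    "fit_loess_trajectories",
    "TrajectoryCluster",
    "cluster_trajectories",
    "SwanCurve",
    "deswan",
]


def _ols_term_test(X: np.ndarray, Y: np.ndarray, term: int):
    """Vectorized OLS of every row of Y on X; t-test for one coefficient.

    Returns (coef matrix p x n_features, t for ``term``, two-sided p).
    Zero-residual or zero-variance rows yield NaN p.
    """
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y.T  # k x n_features
    resid = Y.T - X @ B
    dof = n - k
    rss = (resid**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss / dof
        se = np.sqrt(sigma2 * XtX_inv[term, term])
        t = B[term] / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p[~np.isfinite(t)] = np.nan
    return B, t, p


def fit_linear_age(
    t: FeatureTable,
    m: SampleMeta,
    q_thresh: float = 0.05,
    sex_covariate: bool = True,
    log_base: float = 10.0,
    offset: float | None = None,
) -> pd.DataFrame:
    """Per-feature linear age model on log10 normalized abundance.

    Returns a DataFrame indexed by feature id with columns ``alpha_hat``
    (intercept), ``beta_age`` (slope per year), ``beta_sex`` (male minus
    female shift; NaN when the sex term is off), ``p_age``, ``q_age``
    (BH across non-degenerate features) and ``direction``
    (increase/decrease/ns).  Features with zero variance are flagged
    ``degenerate`` and excluded from the BH family.
    """
    m = m.aligned_to(t)
    age = m.age.to_numpy(dtype=float)
    if len(np.unique(age)) < 3:
        raise FeatureTableError("need >= 3 distinct ages for the linear model")
    cols = [np.ones_like(age), age]
    if sex_covariate:
        male = (m.sex == "M").to_numpy(dtype=float)
        if len(np.unique(male)) < 2:
            raise FeatureTableError("sex covariate requested but only one sex present")
        cols.append(male)
    X = np.column_stack(cols)
    Y = log_transform(t, base=log_base, offset=offset).to_numpy()
    zero_var = Y.std(axis=1) == 0
    B, t_stat, p = _ols_term_test(X, Y, term=1)
    p = p.copy()
    p[zero_var] = np.nan
    q = np.full_like(p, np.nan)
    valid = np.isfinite(p)
    if valid.any():
        q[valid] = bh_adjust(p[valid])
    direction = np.where(
        ~np.isfinite(q) | (q >= q_thresh),
        "ns",
        np.where(B[1] > 0, "increase", "decrease"),
    )
    result = pd.DataFrame(
        {
            "alpha_hat": B[0],
            "beta_age": B[1],
            "beta_sex": B[2] if sex_covariate else np.nan,
            "p_age": p,
            "q_age": q,
            "direction": direction,
            "degenerate": zero_var,
        },
        index=pd.Index(t.feature_ids, name="feature_id"),
    )
    return result


# ---------------------------------------------------------------------------
# LOESS

@dataclass
class LoessResult:
    """Fitted LOESS trajectories on an age grid.

    ``curves``: fitted values (features x grid ages); ``standardized``:
    the same curves z-scored over the grid (zero-variance curves are
    excluded and listed in ``excluded``).
    """

    grid: np.ndarray
    curves: pd.DataFrame
    standardized: pd.DataFrame
    excluded: list[str]
    span: float
    degree: int


def _loess_smoother(x: np.ndarray, grid: np.ndarray, span: float, degree: int) -> np.ndarray:
    """Linear-smoother matrix L (grid x n): fitted(grid) = L @ y."""
    n = len(x)
    k = int(np.ceil(span * n))
    if k < degree + 2:
        raise FeatureTableError(
            f"span {span} gives {k} local points; need >= {degree + 2} — "
            "increase span"
        )
    L = np.zeros((len(grid), n))
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.sort(d)[k - 1]
        if h == 0:
            h = max(np.sort(d)[-1] * 1e-8, 1e-8)  # duplicate-age guard
        u = np.clip(d / h, 0, 1)
        w = (1 - u**3) ** 3
        if w.sum() == 0:
            w[:] = 1.0
        Xl = np.vander(x - x0, degree + 1, increasing=True)
        WX = Xl * w[:, None]
        # ridge-free weighted LS; lstsq handles rank deficiency at the edges
        coef, *_ = np.linalg.lstsq(Xl.T @ WX, WX.T, rcond=None)
        L[i] = coef[0]  # fitted value at x0 is the constant term
    return L


def fit_loess_trajectories(
    t: FeatureTable,
    m: SampleMeta,
    span: float = 0.75,
    grid: Sequence[float] | None = None,
    degree: int = 2,
    log_base: float = 10.0,
    offset: float | None = None,
) -> LoessResult:
    """LOESS trajectory of every feature's log abundance over age.

    ``grid`` defaults to 50 evenly spaced ages spanning the observed
    range; it must stay within that range.  Curves are z-standardized
    over the grid for clustering; flat curves are flagged and excluded
    from the standardized set.
    """
    m = m.aligned_to(t)
    x = m.age.to_numpy(dtype=float)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < x.min() or grid.max() > x.max():
        raise FeatureTableError("grid extends beyond observed age range")
    if not (0 < span <= 1):
        raise FeatureTableError(f"span must be in (0, 1], got {span}")
    L = _loess_smoother(x, grid, span, degree)
    Y = log_transform(t, base=log_base, offset=offset).to_numpy()
    fitted = Y @ L.T  # features x grid
    curves = pd.DataFrame(fitted, index=t.feature_ids, columns=np.round(grid, 6))
    sd = fitted.std(axis=1)
    excluded = [f for f, s in zip(t.feature_ids, sd) if s == 0]
    keep = sd > 0
    standardized = pd.DataFrame(
        (fitted[keep] - fitted[keep].mean(axis=1, keepdims=True))
        / fitted[keep].std(axis=1, keepdims=True),
        index=[f for f, k_ in zip(t.feature_ids, keep) if k_],
        columns=curves.columns,
    )
    return LoessResult(
        grid=grid, curves=curves, standardized=standardized,
        excluded=excluded, span=span, degree=degree,
    )


# ---------------------------------------------------------------------------
# Trajectory clustering

@dataclass
class TrajectoryCluster:
    cluster_id: int
    member_features: list[str]
    mean_curve: pd.Series


def cluster_trajectories(
    curves: pd.DataFrame,
    k: int = 8,
    method: str = "complete",
) -> list[TrajectoryCluster]:
    """Agglomerative clustering of standardized trajectories into k groups.

    Euclidean distance, complete linkage by default (ward/average via
    ``method``).  Raises when fewer than k curves are supplied or when
    ties collapse the tree below k distinct clusters (e.g. identical
    curves).
    """
    n = len(curves)
    if k > n:
        raise FeatureTableError(f"k = {k} exceeds number of curves ({n})")
    Z = linkage(curves.to_numpy(), method=method, metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    found = np.unique(labels)
    if len(found) < k:
        raise FeatureTableError(
            f"only {len(found)} distinct clusters at k = {k} "
            "(identical curves collapse the tree)"
        )
    clusters = []
    for cid in sorted(found):
        members = [f for f, l in zip(curves.index, labels) if l == cid]
        mean_curve = curves.loc[members].mean(axis=0)
        clusters.append(
            TrajectoryCluster(cluster_id=int(cid), member_features=members,
                              mean_curve=mean_curve)
        )
    return clusters


# ---------------------------------------------------------------------------
# DE-SWAN

@dataclass
class SwanCurve:
    """Sliding-window differential-expression curve over age centers."""

    centers: np.ndarray
    n_sig: np.ndarray
    window: float
    q_thresh: float
    peaks: list[float] = field(default_factory=list)
    skipped: list[tuple[float, str]] = field(default_factory=list)
    per_center_q: dict[float, pd.Series] = field(default_factory=dict)
    per_center_p: dict[float, pd.Series] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"center": self.centers, "n_sig": self.n_sig,
             "is_peak": [c in self.peaks for c in self.centers]}
        ).set_index("center")


def _call_peaks(centers: np.ndarray, n_sig: np.ndarray, radius: float = 5.0) -> list[float]:
    """A center is a peak iff it is the maximum within +/- radius years and
    exceeds the curve's median level by >= 2 median absolute deviations."""
    if len(centers) == 0:
        return []
    med = np.median(n_sig)
    mad = np.median(np.abs(n_sig - med))
    floor = med + 2 * mad
    peaks = []
    for i, c in enumerate(centers):
        near = np.abs(centers - c) <= radius
        if n_sig[i] >= n_sig[near].max() and n_sig[i] > floor:
            # collapse plateaus: only the first center of a tied run
            earlier = near & (centers < c)
            if earlier.any() and n_sig[earlier].max() == n_sig[i]:
                continue
            peaks.append(float(c))
    return peaks


def deswan(
    t: FeatureTable,
    m: SampleMeta,
    centers: Sequence[float] | None = None,
    window: float = 20.0,
    q_thresh: float = 0.05,
    sex_covariate: bool = True,
    min_side: int = 3,
    peak_radius: float = 5.0,
    log_base: float = 10.0,
    offset: float | None = None,
    keep_q: bool = False,
) -> SwanCurve:
    """Sliding-window differential expression across age.

    For each center c the young stratum is ages in [c - window/2, c) and
    the old stratum ages in (c, c + window/2]; samples at exactly c are
    excluded.  Each feature is fit by OLS of log10 abundance on the
    stratum indicator (+ sex), the stratum term tested, and q-values
    BH-adjusted across features within the center.  Centers with fewer
    than ``min_side`` samples on either side are skipped and recorded.

    ``centers`` defaults to 1-year steps across the observed age range.
    """
    if window <= 0:
        raise FeatureTableError("window must be positive")
    m = m.aligned_to(t)
    age = m.age.to_numpy(dtype=float)
    if centers is None:
        centers = np.arange(np.floor(age.min()) + 1.0, np.ceil(age.max()), 1.0)
    centers = np.asarray(centers, dtype=float)
    Y_all = log_transform(t, base=log_base, offset=offset).to_numpy()
    male_all = (m.sex == "M").to_numpy(dtype=float)

    used_centers: list[float] = []
    n_sig: list[int] = []
    skipped: list[tuple[float, str]] = []
    per_center_q: dict[float, pd.Series] = {}
    per_center_p: dict[float, pd.Series] = {}
    half = window / 2.0
    for c in centers:
        young = (age >= c - half) & (age < c)
        old = (age > c) & (age <= c + half)
        if young.sum() < min_side or old.sum() < min_side:
            skipped.append(
                (float(c), f"young={int(young.sum())}, old={int(old.sum())} "
                           f"(need >= {min_side} each)")
            )
            continue
        sel = young | old
        stratum = old[sel].astype(float)  # 1 = old stratum
        cols = [np.ones(sel.sum()), stratum]
        if sex_covariate and len(np.unique(male_all[sel])) > 1:
            cols.append(male_all[sel])
        X = np.column_stack(cols)
        _, _, p = _ols_term_test(X, Y_all[:, sel], term=1)
        valid = np.isfinite(p)
        q = np.full_like(p, np.nan)
        if valid.any():
            q[valid] = bh_adjust(p[valid])
        count = int(np.nansum(q < q_thresh))
        used_centers.append(float(c))
        n_sig.append(count)
        if keep_q:
            per_center_q[float(c)] = pd.Series(q, index=t.feature_ids)
            per_center_p[float(c)] = pd.Series(p, index=t.feature_ids)
    used = np.asarray(used_centers)
    counts = np.asarray(n_sig, dtype=int)
    curve = SwanCurve(
        centers=used, n_sig=counts, window=window, q_thresh=q_thresh,
        skipped=skipped, per_center_q=per_center_q, per_center_p=per_center_p,
    )
    curve.peaks = _call_peaks(used, counts, radius=peak_radius)
    if skipped:
        warnings.warn(
            f"deswan skipped {len(skipped)} underpopulated centers", stacklevel=2
        )
    return curve
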