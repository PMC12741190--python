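"""Elastic-net aging clocks, reduced clocks, and biomarker panels.

An aging clock is a penalized linear model predicting chronological age
from log-transformed feature abundances.  Elastic net mixes L1 (sparsity)
and L2 (shrinkage) penalties through the mixing parameter alpha; the
penalty strength lambda is optimized by k-fold cross-validation on the
training split, and the final model is the (alpha, train-fraction,
lambda) combination with the smallest mean absolute error (MAE, years)
on the held-out test split.  Features are standardized to zero mean and
unit variance inside every fit, so predictions are invariant to
per-feature affine rescaling of the inputs.

The reduced clock ranks the selected features by absolute standardized
coefficient, refits clocks on the top 2, 3, 4, ... features, and fits a
two-segment (broken-stick) regression to the accuracy-versus-size curve;
the knot is the point of diminishing returns and sets the reduced model
size.

The biomarker panel intersects three feature sets — up in the elderly
(>= 65 vs < 40 years), linearly increasing with age, carrying nonzero
clock weight — and evaluates a penalized logistic classifier of elderly
vs young with stratified cross-validated ROC analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .core_tables import (
    FeatureTable,
    FeatureTableError,
    SampleMeta,
    log_transform,
)

__all__ = [
    "ClockModel",
    "fit_clock",
    "ReducedClock",
    "reduce_clock",
    "broken_stick_fit",
    "PanelSelection",
    "select_panel",
    "PanelResult",
    "fit_panel_classifier",
    "clock_design",
]

DEFAULT_ALPHA_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)
DEFAULT_TRAIN_FRACTIONS = (0.5, 0.6, 0.7, 0.8)


def clock_design(
    tables: FeatureTable | Sequence[FeatureTable],
    log_base: float = 10.0,
    offset: float | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Samples-by-features design matrix from one or more tables.

    Tables are log-transformed independently and concatenated on shared
    samples; feature ids must be disjoint across tables (metabolite names
    and lipid shorthand naturally are).  Returns the design and a
    feature -> modality map.
    """
    if isinstance(tables, FeatureTable):
        tables = [tables]
    shared = list(tables[0].sample_ids)
    for t in tables[1:]:
        shared = [s for s in shared if s in set(t.sample_ids)]
    if not shared:
        raise FeatureTableError("tables share no samples")
    blocks = []
    modality: dict[str, str] = {}
    for t in tables:
        block = log_transform(t, base=log_base, offset=offset).T.loc[shared]
        dup = set(block.columns) & set(modality)
        if dup:
            raise FeatureTableError(f"duplicate feature ids across tables: {sorted(dup)[:5]}")
        for f in block.columns:
            modality[f] = t.modality
        blocks.append(block)
    return pd.concat(blocks, axis=1), modality


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return (X - mean) / scale, mean, scale


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int) -> np.ndarray:
    yc = y - y.mean()
    lam_max = np.abs(Xs.T @ yc).max() / (len(y) * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-3), n_lambda)


def _cv_lambda(
    Xs: np.ndarray, y: np.ndarray, alpha: float, lambdas: np.ndarray,
    cv: int, seed: int,
) -> tuple[float, float]:
    """Mean-CV-MAE-minimizing lambda on already-standardized training data."""
    kf = KFold(n_splits=min(cv, len(y)), shuffle=True, random_state=seed)
    maes = np.zeros(len(lambdas))
    for tr, va in kf.split(Xs):
        mu, sd = Xs[tr].mean(axis=0), Xs[tr].std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xtr, Xva = (Xs[tr] - mu) / sd, (Xs[va] - mu) / sd
        for i, lam in enumerate(lambdas):
            net = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=5000, tol=1e-5)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net.fit(Xtr, y[tr])
            maes[i] += np.abs(net.predict(Xva) - y[va]).mean()
    maes /= kf.get_n_splits()
    best = int(np.argmin(maes))
    return float(lambdas[best]), float(maes[best])


@dataclass
class ClockModel:
    """Fitted aging clock: coefficients, selection trace and test accuracy.

    ``coefficients`` are on the standardized-feature scale; ``predict``
    applies the stored standardization.  ``selection_trace`` records the
    test MAE of every (alpha, train fraction) candidate.
    """

    feature_ids: list[str]
    coefficients: pd.Series  # standardized scale, all features
    intercept: float
    scaler_mean: pd.Series
    scaler_scale: pd.Series
    alpha: float
    lam: float
    train_fraction: float
    mae_test: float
    r_test: float
    predictions: pd.DataFrame  # sample_id -> age, predicted_age, split
    selection_trace: pd.DataFrame
    modality: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    @property
    def nonzero_features(self) -> list[str]:
        return list(self.coefficients.index[self.coefficients != 0])

    def predict(self, X: pd.DataFrame) -> pd.Series:
        Xs = (X[self.feature_ids] - self.scaler_mean) / self.scaler_scale
        return pd.Series(
            Xs.to_numpy() @ self.coefficients.to_numpy() + self.intercept,
            index=X.index, name="predicted_age",
        )

    def summary(self) -> str:
        lines = [
            "Aging clock (elastic net)",
            f"  features in design    : {len(self.feature_ids)}",
            f"  nonzero coefficients  : {len(self.nonzero_features)}",
            f"  alpha (L1 mixing)     : {self.alpha}",
            f"  lambda (penalty)      : {self.lam:.6g}",
            f"  train fraction        : {self.train_fraction}",
            f"  test MAE (years)      : {self.mae_test:.3f}",
            f"  test Pearson r        : {self.r_test:.3f}",
        ]
        top = self.coefficients[self.coefficients != 0]
        top = top.reindex(top.abs().sort_values(ascending=False).index)[:10]
        if len(top):
            lines.append("  top coefficients (standardized):")
            for f, c in top.items():
                lines.append(f"    {f:<40s} {c:+.4f}")
        return "\n".join(lines)


def _split_seed(seed: int, tag: int) -> int:
    return (seed * 1000003 + tag * 7919 + 17) % (2**31 - 1)


def fit_clock(
    tables: FeatureTable | Sequence[FeatureTable],
    m: SampleMeta,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    train_fractions: Sequence[float] = DEFAULT_TRAIN_FRACTIONS,
    seed: int = 0,
    cv: int = 10,
    n_lambda: int = 20,
    feature_subset: Sequence[str] | None = None,
    offset: float | None = None,
) -> ClockModel:
    """Fit the elastic-net aging clock with full model selection.

    For every (alpha, train fraction) pair: a stratified (by life-stage
    group) train/test split, lambda chosen by ``cv``-fold CV on the
    training split, and MAE measured on the test split.  The combination
    with the smallest test MAE wins; its model, refit on the training
    split, is returned.  Deterministic given ``seed``.
    """
    if any(not (0 < a < 1) for a in alpha_grid):
        raise FeatureTableError("alpha_grid values must lie in (0, 1)")
    if any(f < 0.5 for f in train_fractions):
        raise FeatureTableError("train_fractions must be >= 0.5")
    X_df, modality = clock_design(tables, offset=offset)
    if feature_subset is not None:
        X_df = X_df[list(feature_subset)]
    m = m.aligned_to(
        tables if isinstance(tables, FeatureTable) else tables[0]
    )
    m_tab = m.table.loc[X_df.index]
    if len(X_df) < 30:
        raise FeatureTableError("clock fitting needs >= 30 samples")
    y = m_tab["age"].to_numpy(dtype=float)
    groups = m_tab["group"].astype(str).to_numpy()
    sample_ids = np.array(X_df.index)
    X = X_df.to_numpy()

    trace_rows = []
    best = None
    for fi, frac in enumerate(train_fractions):
        strat = groups if min(np.bincount(pd.factorize(groups)[0])) >= 2 else None
        tr_idx, te_idx = train_test_split(
            np.arange(len(y)), train_size=frac,
            random_state=_split_seed(seed, fi), stratify=strat,
        )
        if len(te_idx) == 0:
            raise FeatureTableError(f"train fraction {frac} leaves an empty test set")
        Xtr_s, mu, sd = _standardize(X[tr_idx])
        Xte_s = (X[te_idx] - mu) / sd
        for alpha in alpha_grid:
            lambdas = _lambda_grid(Xtr_s, y[tr_idx], alpha, n_lambda)
            lam, cv_mae = _cv_lambda(X[tr_idx], y[tr_idx], alpha, lambdas, cv,
                                     _split_seed(seed, 500 + fi))
            net = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=10000, tol=1e-6)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net.fit(Xtr_s, y[tr_idx])
            pred_te = net.predict(Xte_s)
            mae = float(np.abs(pred_te - y[te_idx]).mean())
            trace_rows.append(
                {"alpha": alpha, "train_fraction": frac, "lambda": lam,
                 "cv_mae_train": cv_mae, "mae_test": mae,
                 "n_nonzero": int((net.coef_ != 0).sum())}
            )
            if best is None or mae < best["mae"]:
                best = {
                    "mae": mae, "alpha": alpha, "frac": frac, "lam": lam,
                    "net": net, "mu": mu, "sd": sd,
                    "tr_idx": tr_idx, "te_idx": te_idx,
                }

    net = best["net"]
    mu, sd = best["mu"], best["sd"]
    pred_all = ((X - mu) / sd) @ net.coef_ + net.intercept_
    split = np.full(len(y), "train", dtype=object)
    split[best["te_idx"]] = "test"
    predictions = pd.DataFrame(
        {"age": y, "predicted_age": pred_all, "split": split},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    te = predictions[predictions["split"] == "test"]
    r_test = float(stats.pearsonr(te["age"], te["predicted_age"])[0]) if len(te) > 2 else np.nan
    return ClockModel(
        feature_ids=list(X_df.columns),
        coefficients=pd.Series(net.coef_, index=X_df.columns),
        intercept=float(net.intercept_),
        scaler_mean=pd.Series(mu, index=X_df.columns),
        scaler_scale=pd.Series(sd, index=X_df.columns),
        alpha=best["alpha"], lam=best["lam"], train_fraction=best["frac"],
        mae_test=best["mae"], r_test=r_test,
        predictions=predictions,
        selection_trace=pd.DataFrame(trace_rows),
        modality={f: modality.get(f, "metabolite") for f in X_df.columns},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Broken-stick reduction

def broken_stick_fit(
    x: Sequence[float], y: Sequence[float], n_grid: int = 400
) -> tuple[float, np.ndarray, float, bool]:
    """Two-segment continuous piecewise-linear least squares.

    Searches a fine grid of candidate knots between the second and
    second-to-last x, fitting ``y ~ 1 + x + max(x - knot, 0)`` at each,
    and returns (knot, coefficients, sse, low_confidence).  The fit is
    flagged low-confidence when the two-segment model barely improves on
    a single line (slope change indistinguishable from zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise FeatureTableError("broken-stick fit needs >= 4 points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    X1 = np.column_stack([np.ones_like(x), x])
    coef1, res1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    sse1 = float(((y - X1 @ coef1) ** 2).sum())
    candidates = np.linspace(x[1], x[-2], n_grid)
    best_sse, best_knot, best_coef = np.inf, candidates[0], None
    for c in candidates:
        X2 = np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])
        coef, *_ = np.linalg.lstsq(X2, y, rcond=None)
        sse = float(((y - X2 @ coef) ** 2).sum())
        if sse < best_sse - 1e-15:
            best_sse, best_knot, best_coef = sse, float(c), coef
    denom = max(sse1, 1e-12)
    low_confidence = (sse1 - best_sse) / denom < 0.05 or abs(best_coef[2]) < 1e-10
    return best_knot, best_coef, best_sse, bool(low_confidence)


@dataclass
class ReducedClock:
    """Reduced clock: ranked features, accuracy curve and breakpoint."""

    ranked_features: list[str]
    accuracy_curve: pd.DataFrame  # n_features -> accuracy (r or mae)
    knot: float
    breakpoint: int
    low_confidence: bool
    final_model: ClockModel
    metric: str = "r"

    def summary(self) -> str:
        flag = " (low confidence)" if self.low_confidence else ""
        return (
            f"Reduced clock: breakpoint at {self.breakpoint} features"
            f"{flag}; knot = {self.knot:.2f}; metric = {self.metric}\n"
            + self.final_model.summary()
        )


def reduce_clock(
    model: ClockModel,
    tables: FeatureTable | Sequence[FeatureTable],
    m: SampleMeta,
    alpha_grid: Sequence[float] | None = None,
    seed: int = 0,
    train_fraction: float = 0.8,
    metric: str = "r",
    cv: int = 10,
    n_lambda: int = 10,
    max_features: int | None = None,
) -> ReducedClock:
    """Broken-stick model reduction of a fitted clock.

    Features with nonzero coefficients are ranked by absolute
    standardized coefficient (largest contribution first); clocks are
    refit on the top 2, 3, ... features at ``train_fraction`` and the
    accuracy (test-split Pearson r by default, MAE via ``metric="mae"``)
    recorded.  A broken-stick regression of accuracy on feature count
    locates the knot; the breakpoint is the knot rounded to the nearest
    curve point, and the final model is refit at that size.
    """
    ranked = model.coefficients[model.coefficients != 0]
    ranked = list(ranked.reindex(ranked.abs().sort_values(ascending=False).index).index)
    if len(ranked) < 3:
        raise FeatureTableError("reduction needs >= 3 nonzero coefficients")
    if max_features is not None:
        ranked = ranked[:max_features]
    alphas = tuple(alpha_grid) if alpha_grid is not None else DEFAULT_ALPHA_GRID
    sizes = list(range(2, len(ranked) + 1))
    if len(sizes) < 4:
        raise FeatureTableError(
            "accuracy curve would have fewer than 4 points; segmented fit unidentifiable"
        )
    rows = []
    for j in sizes:
        sub = fit_clock(
            tables, m, alpha_grid=alphas, train_fractions=(train_fraction,),
            seed=seed, cv=cv, n_lambda=n_lambda, feature_subset=ranked[:j],
        )
        acc = sub.r_test if metric == "r" else sub.mae_test
        rows.append({"n_features": j, "accuracy": acc, "mae_test": sub.mae_test,
                     "r_test": sub.r_test})
    curve = pd.DataFrame(rows).set_index("n_features")
    knot, _, _, low_conf = broken_stick_fit(
        curve.index.to_numpy(dtype=float), curve["accuracy"].to_numpy()
    )
    breakpoint_ = int(np.clip(round(knot), 2, len(ranked)))
    final = fit_clock(
        tables, m, alpha_grid=alphas, train_fractions=(train_fraction,),
        seed=seed, cv=cv, n_lambda=n_lambda, feature_subset=ranked[:breakpoint_],
    )
    return ReducedClock(
        ranked_features=ranked, accuracy_curve=curve, knot=knot,
        breakpoint=breakpoint_, low_confidence=low_conf, final_model=final,
        metric=metric,
    )


# ---------------------------------------------------------------------------
# Biomarker panel

@dataclass
class PanelSelection:
    """Triple intersection of elderly-up, age-increasing and clock features."""

    elderly_up: set[str]
    age_increasing: set[str]
    clock_selected: set[str]
    intersection: list[str]
    pairwise_counts: dict[str, int]

    def summary(self) -> str:
        return (
            f"Panel selection: |elderly-up| = {len(self.elderly_up)}, "
            f"|age-increasing| = {len(self.age_increasing)}, "
            f"|clock| = {len(self.clock_selected)}, "
            f"triple intersection = {len(self.intersection)}"
        )


def select_panel(
    de_elderly, age_models: pd.DataFrame, clock: ClockModel,
    q_thresh: float = 0.05,
) -> PanelSelection:
    """Intersect the three aging-biomarker criteria.

    ``de_elderly`` is the elderly-vs-young comparison
    (:class:`~lifespanomics.differential.DEComparison`, >= 65 vs < 40);
    ``age_models`` the linear age-model table; ``clock`` the fitted
    elastic net.  All three must share a feature universe.
    """
    universe = set(de_elderly.table.index) & set(age_models.index) & set(clock.feature_ids)
    if not universe:
        raise FeatureTableError("the three inputs share no features")
    set1 = de_elderly.significant("up") & universe
    am = age_models.loc[sorted(universe)]
    set2 = set(am.index[(am["q_age"] < q_thresh) & (am["beta_age"] > 0)])
    set3 = set(clock.nonzero_features) & universe
    pairwise = {
        "elderly_up&age_increasing": len(set1 & set2),
        "elderly_up&clock": len(set1 & set3),
        "age_increasing&clock": len(set2 & set3),
    }
    return PanelSelection(
        elderly_up=set1, age_increasing=set2, clock_selected=set3,
        intersection=sorted(set1 & set2 & set3), pairwise_counts=pairwise,
    )


@dataclass
class PanelResult:
    """Cross-validated elderly-vs-young classifier on the selected panel."""

    selected_features: list[str]
    coefficients: pd.Series
    intercept: float
    cv_auc_mean: float
    fold_aucs: list[float]
    roc_points: pd.DataFrame  # fpr, tpr, threshold, fold
    n_folds: int

    def summary(self) -> str:
        return (
            f"Biomarker panel ({len(self.selected_features)} features): "
            f"mean {self.n_folds}-fold CV AUC = {self.cv_auc_mean:.3f}"
        )


def fit_panel_classifier(
    features: Sequence[str],
    tables: FeatureTable | Sequence[FeatureTable],
    m: SampleMeta,
    k_folds: int = 10,
    seed: int = 0,
    elderly_age: float = 65.0,
    young_age: float = 40.0,
    C: float = 1.0,
) -> PanelResult:
    """Penalized logistic classifier of elderly (>= 65) vs young (< 40).

    Middle-aged samples (40–64 years) are excluded.  Stratified k-fold
    cross-validation with per-fold standardization; ROC points and AUC
    recorded per fold, and the final coefficients come from a fit on all
    elderly/young samples.  Fold count is reduced (with a warning) when
    the smaller class has fewer members than ``k_folds``.
    """
    X_df, _ = clock_design(tables)
    X_df = X_df[list(features)]
    ages = m.table.loc[X_df.index, "age"].to_numpy(dtype=float)
    elderly = ages >= elderly_age
    young = ages < young_age
    keep = elderly | young
    X = X_df.to_numpy()[keep]
    ylab = elderly[keep].astype(int)
    n_min = min(ylab.sum(), (1 - ylab).sum())
    if n_min < 2:
        raise FeatureTableError("each class needs >= 2 samples")
    folds = int(min(k_folds, n_min))
    if folds < k_folds:
        warnings.warn(
            f"reducing folds from {k_folds} to {folds}: smaller class has "
            f"{n_min} members", stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs = []
    roc_rows = []
    for fold, (tr, te) in enumerate(skf.split(X, ylab)):
        Xtr, mu, sd = _standardize(X[tr])
        Xte = (X[te] - mu) / sd
        clf = LogisticRegression(C=C, max_iter=2000)
        clf.fit(Xtr, ylab[tr])
        scores = clf.decision_function(Xte)
        if len(np.unique(ylab[te])) < 2:
            continue  # AUC undefined on a single-class fold
        fold_aucs.append(float(roc_auc_score(ylab[te], scores)))
        fpr, tpr, thr = roc_curve(ylab[te], scores)
        for f_, t_, th in zip(fpr, tpr, thr):
            roc_rows.append({"fpr": f_, "tpr": t_, "threshold": th, "fold": fold})
    Xall, mu, sd = _standardize(X)
    clf = LogisticRegression(C=C, max_iter=2000)
    clf.fit(Xall, ylab)
    return PanelResult(
        selected_features=list(features),
        coefficients=pd.Series(clf.coef_[0], index=list(features)),
        intercept=float(clf.intercept_[0]),
        cv_auc_mean=float(np.mean(fold_aucs)) if fold_aucs else np.nan,
        fold_aucs=fold_aucs,
        roc_points=pd.DataFrame(roc_rows, columns=["fpr", "tpr", "threshold", "fold"]),
        n_folds=folds,
    )
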