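"""PCA, principal variance component analysis, and correlation networks.

PVCA projects the log2 abundance matrix onto its leading principal
components, decomposes each retained PC's variance into random-effect
contributions of the design factors — age (the seven life-stage groups,
treated categorically), sex, and their interaction — plus residual, and
averages the per-PC fractions weighted by eigenvalue.  Variance
components are estimated by REML (a mixed model with one variance
component per factor); when REML fails to converge a method-of-moments
fallback is used and noted in the result.

The metabolite–lipid correlation network scores all cross-pairs of the
top age-associated features on each side with Spearman's rank
correlation (average ranks for ties), keeping edges above an absolute
correlation threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_tables import (
    FeatureTable,
    FeatureTableError,
    SampleMeta,
    log_transform,
)

__all__ = [
    "pca_scores",
    "PvcaResult",
    "pvca",
    "spearman_network",
    "network_to_graphml",
]


def pca_scores(
    t: FeatureTable,
    n_components: int | None = None,
    log_base: float = 2.0,
    offset: float | None = None,
    scale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and explained-variance fractions of a PCA.

    Features are log2-transformed and centered (optionally unit-scaled);
    constant features are dropped with a warning.  Returns a DataFrame of
    scores (samples x components) and the explained-variance fractions.
    """
    if t.n_samples < 2:
        raise FeatureTableError("PCA needs more than one sample")
    X = log_transform(t, base=log_base, offset=offset).to_numpy().T  # samples x features
    sd = X.std(axis=0)
    if (sd == 0).any():
        warnings.warn(f"dropping {int((sd == 0).sum())} constant features", stacklevel=2)
        X = X[:, sd > 0]
        sd = sd[sd > 0]
    X = X - X.mean(axis=0)
    if scale:
        X = X / sd
    n_max = min(X.shape)
    k = n_max if n_components is None else min(n_components, n_max)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    frac = var / var.sum()
    scores = U[:, :k] * s[:k]
    df = pd.DataFrame(
        scores, index=t.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return df, frac[:k]


@dataclass
class PvcaResult:
    """Eigenvalue-weighted variance fractions per design factor."""

    fractions: pd.Series  # index: age, sex, age_sex, residual; sums to 1
    n_components: int
    variance_kept: float
    per_pc: pd.DataFrame = field(default_factory=pd.DataFrame)
    fallback_pcs: list[int] = field(default_factory=list)


def _reml_components(y: np.ndarray, factor_codes: dict[str, np.ndarray]) -> dict[str, float] | None:
    """REML variance components for crossed random intercepts; None on failure.

    Failure includes any optimizer convergence warning — boundary
    estimates for few-level factors can otherwise pass through as
    arbitrarily inflated components.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = pd.DataFrame({"y": y, "one": 1})
    vc_formula = {}
    for name, codes in factor_codes.items():
        df[name] = pd.Categorical(codes)
        vc_formula[name] = f"0 + C({name})"
    df["g"] = 1  # single grouping level: all components crossed
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            model = sm.MixedLM.from_formula(
                "y ~ 1", groups="g", vc_formula=vc_formula, re_formula="0", data=df
            )
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        if not np.all(np.isfinite(fit.params)) or not getattr(fit, "converged", False):
            return None
        comps = {name: max(float(fit.vcomp[i]), 0.0)
                 for i, name in enumerate(model.exog_vc.names)}
        comps["residual"] = max(float(fit.scale), 0.0)
        return comps
    except Exception:
        return None


def _anova_component(y: np.ndarray, codes: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA variance component (clipped at 0) and within mean square."""
    s = pd.Series(y)
    g = s.groupby(pd.Categorical(codes), observed=True)
    counts = g.size().to_numpy(dtype=float)
    a = len(counts)
    N = float(len(y))
    if a < 2:
        return 0.0, float(np.var(y, ddof=1))
    means = g.mean().to_numpy()
    grand = y.mean()
    msb = float(np.sum(counts * (means - grand) ** 2) / (a - 1))
    ssw = float(sum(((s[np.asarray(codes) == lvl] - mu) ** 2).sum()
                    for lvl, mu in zip(g.mean().index, means)))
    msw = ssw / max(N - a, 1.0)
    n0 = (N - np.sum(counts**2) / N) / (a - 1)
    return max((msb - msw) / n0, 0.0), msw


def _moments_components(y: np.ndarray, factor_codes: dict[str, np.ndarray]) -> dict[str, float]:
    """Method-of-moments fallback via one-way ANOVA per factor.

    Main factors get the classical (MSB - MSW) / n0 estimator, clipped
    at zero; the interaction is the combined-factor component net of the
    main effects; the residual is the within-cell mean square of the
    combined factor.
    """
    comps: dict[str, float] = {}
    msw_comb = float(np.var(y, ddof=1))
    main_total = 0.0
    for name, codes in factor_codes.items():
        if name == "age_sex":
            continue
        comps[name], _ = _anova_component(y, codes)
        main_total += comps[name]
    if "age_sex" in factor_codes:
        comb, msw_comb = _anova_component(y, factor_codes["age_sex"])
        comps["age_sex"] = max(comb - main_total, 0.0)
    comps["residual"] = max(msw_comb, 1e-12)
    return comps


def pvca(
    t: FeatureTable,
    m: SampleMeta,
    variance_kept: float = 0.6,
    n_components: int | None = None,
    log_base: float = 2.0,
    offset: float | None = None,
) -> PvcaResult:
    """Principal variance component analysis over age, sex and age x sex.

    PCs are retained up to ``variance_kept`` cumulative explained
    variance (or exactly ``n_components`` if given).  Age enters as the
    categorical life-stage group.  Single-level factors contribute a zero
    fraction with a warning.  Fractions are normalized to sum to 1.
    """
    m = m.aligned_to(t)
    scores, frac = pca_scores(t, log_base=log_base, offset=offset)
    if n_components is not None:
        k = n_components
    else:
        k = int(np.searchsorted(np.cumsum(frac), variance_kept) + 1)
        k = min(k, scores.shape[1])
    group = m.group.astype(str).to_numpy()
    sex = m.sex.to_numpy()
    factor_codes = {
        "age": group,
        "sex": sex,
        "age_sex": np.char.add(np.char.add(group.astype(str), ":"), sex.astype(str)),
    }
    for name in ("age", "sex"):
        if len(np.unique(factor_codes[name])) < 2:
            warnings.warn(f"factor {name!r} has a single level; fraction will be 0",
                          stacklevel=2)
    rows = []
    fallback = []
    for i in range(k):
        y = scores.iloc[:, i].to_numpy()
        comps = _reml_components(y, factor_codes)
        if comps is None:
            comps = _moments_components(y, factor_codes)
            fallback.append(i + 1)
        total = sum(comps.values())
        if total <= 0:
            comps = {name: 0.0 for name in comps}
            comps["residual"] = 1.0
            total = 1.0
        rows.append({name: comps.get(name, 0.0) / total
                     for name in ("age", "sex", "age_sex", "residual")})
    per_pc = pd.DataFrame(rows, index=[f"PC{i + 1}" for i in range(k)])
    weights = frac[:k] / frac[:k].sum()
    weighted = per_pc.mul(weights, axis=0).sum(axis=0)
    fractions = weighted / weighted.sum()
    if fallback:
        warnings.warn(
            f"REML did not converge for PCs {fallback}; method-of-moments used",
            stacklevel=2,
        )
    return PvcaResult(
        fractions=fractions, n_components=k,
        variance_kept=float(np.cumsum(frac)[k - 1]),
        per_pc=per_pc, fallback_pcs=fallback,
    )


# ---------------------------------------------------------------------------
# Metabolite–lipid correlation network

def spearman_network(
    metab: FeatureTable,
    lipid: FeatureTable,
    metab_age_models: pd.DataFrame,
    lipid_age_models: pd.DataFrame,
    top_n: int = 50,
    rho_thresh: float = 0.5,
    p_thresh: float = 0.05,
    q_thresh: float = 0.05,
) -> pd.DataFrame:
    """Cross-modality Spearman edges between top age-associated features.

    Endpoints are the ``top_n`` features per side with the largest
    absolute linear age slope among those significant at
    ``q_age < q_thresh`` (age-model tables from
    :func:`~lifespanomics.trajectory.fit_linear_age`).  All cross-pairs
    are scored on the shared samples; edges with |rho| > ``rho_thresh``
    and p < ``p_thresh`` are kept, annotated with both endpoints' slopes.
    """
    shared = [s for s in metab.sample_ids if s in set(lipid.sample_ids)]
    if not shared:
        raise FeatureTableError("metabolite and lipid tables share no samples")

    def _top(models: pd.DataFrame, table: FeatureTable) -> list[str]:
        sub = models.loc[models.index.intersection(table.feature_ids)]
        sig = sub[(sub["q_age"] < q_thresh) & np.isfinite(sub["q_age"])]
        ranked = sig.reindex(sig["beta_age"].abs().sort_values(ascending=False).index)
        return list(ranked.index[:top_n])

    top_m = _top(metab_age_models, metab)
    top_l = _top(lipid_age_models, lipid)
    rows = []
    if top_m and top_l:
        Xm = metab.data.loc[top_m, shared].to_numpy()
        Xl = lipid.data.loc[top_l, shared].to_numpy()
        rho_mat, p_mat = stats.spearmanr(Xm.T, Xl.T)
        nm = len(top_m)
        rho_cross = np.atleast_2d(rho_mat)[:nm, nm:]
        p_cross = np.atleast_2d(p_mat)[:nm, nm:]
        for i, fm in enumerate(top_m):
            for j, fl in enumerate(top_l):
                rho = float(rho_cross[i, j])
                p = float(p_cross[i, j])
                if abs(rho) > rho_thresh and p < p_thresh:
                    rows.append(
                        {"feature_a": fm, "feature_b": fl, "rho": rho, "p": p,
                         "beta_a": float(metab_age_models.loc[fm, "beta_age"]),
                         "beta_b": float(lipid_age_models.loc[fl, "beta_age"])}
                    )
    return pd.DataFrame(
        rows, columns=["feature_a", "feature_b", "rho", "p", "beta_a", "beta_b"]
    )


def network_to_graphml(edges: pd.DataFrame, path) -> None:
    """Write an edge list as GraphML (Cytoscape-loadable)."""
    import networkx as nx

    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_node(row["feature_a"], side="metabolite", beta=float(row["beta_a"]))
        g.add_node(row["feature_b"], side="lipid", beta=float(row["beta_b"]))
        g.add_edge(row["feature_a"], row["feature_b"],
                   rho=float(row["rho"]), p=float(row["p"]))
    nx.write_graphml(g, path)
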