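"""Group-wise differential profiling, marker discovery and enrichment.

Two-group comparisons use a two-sided t test on log10-transformed
normalized abundances (Welch unequal-variance form by default — life-stage
groups have plainly unequal spreads; a pooled-variance switch is provided),
with Benjamini–Hochberg adjustment across all features of one comparison.

Pathway over-representation is the one-sided hypergeometric (Fisher) test
over a GMT-defined pathway collection, again BH-adjusted.  Class-level
change scores summarize a comparison as (n_up - n_down) / n_class over a
feature→class map.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_tables import (
    LIFE_STAGE_GROUPS,
    FeatureTable,
    FeatureTableError,
    SampleMeta,
    log_transform,
)

__all__ = [
    "bh_adjust",
    "de_two_groups",
    "newborn_contrasts",
    "group_markers",
    "change_score",
    "enrich",
    "read_gmt",
]


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEComparison:
    """Result of one two-group comparison: per-feature table plus labels."""

    group_a: str
    group_b: str
    table: pd.DataFrame  # feature_id, log2fc, t_stat, p, q, direction

    def significant(self, direction: str | None = None) -> set[str]:
        tab = self.table[self.table["direction"] != "ns"]
        if direction is not None:
            tab = tab[tab["direction"] == direction]
        return set(tab.index)


def de_two_groups(
    t: FeatureTable,
    m: SampleMeta,
    group_a: str,
    group_b: str,
    q_thresh: float = 0.05,
    equal_var: bool = False,
    log_base: float = 10.0,
    offset: float | None = None,
) -> DEComparison:
    """Two-sided t test of every feature between two sample sets.

    ``group_a``/``group_b`` are life-stage labels, or explicit sample-id
    lists for ad-hoc contrasts (e.g. elderly vs young by age cut-off).
    ``log2fc`` is log2 of the ratio of group means on the normalized
    scale; ``direction`` is up/down (sign of the a-vs-b difference) for
    q < ``q_thresh``, else ``ns``.  Zero-variance features with equal
    means are degenerate: flagged ``ns`` with p = q = NaN.
    """
    m = m.aligned_to(t)
    ids_a = _resolve_samples(m, group_a)
    ids_b = _resolve_samples(m, group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise FeatureTableError(
            f"both groups need >= 2 samples (got {len(ids_a)}, {len(ids_b)})"
        )
    log_data = log_transform(t, base=log_base, offset=offset)
    xa = log_data[ids_a].to_numpy()
    xb = log_data[ids_b].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(xa, xb, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(p)
    p_valid = p[~degenerate]
    q = np.full_like(p, np.nan)
    if p_valid.size:
        q[~degenerate] = bh_adjust(p_valid)

    mean_a = t.data[ids_a].mean(axis=1).to_numpy()
    mean_b = t.data[ids_b].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_a / mean_b)

    direction = np.where(
        ~np.isfinite(q) | (q >= q_thresh),
        "ns",
        np.where(t_stat > 0, "up", "down"),
    )
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_stat": t_stat,
            "p": p,
            "q": q,
            "direction": direction,
        },
        index=pd.Index(t.feature_ids, name="feature_id"),
    )
    ga = group_a if isinstance(group_a, str) else "set_a"
    gb = group_b if isinstance(group_b, str) else "set_b"
    return DEComparison(group_a=ga, group_b=gb, table=table)


def _resolve_samples(m: SampleMeta, group) -> list[str]:
    if isinstance(group, str):
        return m.samples_in_group(group)
    return list(group)


def newborn_contrasts(
    t: FeatureTable, m: SampleMeta, q_thresh: float = 0.05
) -> tuple[dict[str, DEComparison], pd.DataFrame]:
    """Newborns versus each other life-stage group, plus intersection counts.

    Returns the six comparisons (newborn vs B..G) and an upset-style
    count table: one row per nonempty combination of comparisons in which
    a feature is significant, with the count of features significant in
    exactly that combination.
    """
    m = m.aligned_to(t)
    if not m.samples_in_group("A_newborn"):
        raise FeatureTableError("no newborn samples")
    others = [g for g in LIFE_STAGE_GROUPS[1:] if m.samples_in_group(g)]
    comparisons = {
        g: de_two_groups(t, m, "A_newborn", g, q_thresh=q_thresh) for g in others
    }
    sig_sets = {g: c.significant() for g, c in comparisons.items()}
    membership: dict[str, tuple[str, ...]] = {}
    for f in t.feature_ids:
        combo = tuple(g for g in others if f in sig_sets[g])
        if combo:
            membership.setdefault(f, combo)
    counts: dict[tuple[str, ...], int] = {}
    for combo in membership.values():
        counts[combo] = counts.get(combo, 0) + 1
    rows = [
        {"comparisons": "&".join(combo), "n_groups": len(combo), "count": n}
        for combo, n in sorted(counts.items(), key=lambda kv: (-len(kv[0]), kv[0]))
    ]
    table = pd.DataFrame(rows, columns=["comparisons", "n_groups", "count"])
    return comparisons, table


def group_markers(
    t: FeatureTable, m: SampleMeta, q_thresh: float = 0.05
) -> dict[str, list[str]]:
    """Features specifically elevated in one life-stage group.

    A feature marks group g when it is significantly up (q < threshold)
    in g versus the pooled remaining samples AND its group mean (on the
    normalized scale) is maximal in g — the second condition enforces
    specificity.
    """
    m = m.aligned_to(t)
    groups = [g for g in LIFE_STAGE_GROUPS if m.samples_in_group(g)]
    if len(groups) < 2:
        raise FeatureTableError("group markers need >= 2 groups")
    group_means = pd.DataFrame(
        {g: t.data[m.samples_in_group(g)].mean(axis=1) for g in groups}
    )
    argmax = group_means.idxmax(axis=1)
    markers: dict[str, list[str]] = {}
    for g in groups:
        in_g = m.samples_in_group(g)
        rest = [s for s in t.sample_ids if s not in set(in_g)]
        comp = de_two_groups(t, m, in_g, rest, q_thresh=q_thresh)
        up = comp.significant("up")
        markers[g] = sorted(f for f in up if argmax[f] == g)
    return markers


def change_score(
    de: DEComparison, class_map: Mapping[str, str]
) -> pd.DataFrame:
    """Signed per-class change score: (n_up - n_down) / n_class.

    ``class_map`` assigns each feature to a class (e.g. a lipid class or
    metabolite category).  Scores lie in [-1, 1]; classes with no
    features in the comparison are flagged undefined.
    """
    missing = set(de.table.index) - set(class_map)
    if missing:
        raise ValueError(f"class_map missing features: {sorted(missing)[:5]}")
    rows = []
    classes = sorted(set(class_map[f] for f in de.table.index))
    direction = de.table["direction"]
    for cls in classes:
        members = [f for f in de.table.index if class_map[f] == cls]
        n = len(members)
        if n == 0:
            rows.append({"class": cls, "score": np.nan, "n_up": 0, "n_down": 0,
                         "n_class": 0, "defined": False})
            continue
        n_up = int((direction[members] == "up").sum())
        n_down = int((direction[members] == "down").sum())
        rows.append(
            {"class": cls, "score": (n_up - n_down) / n, "n_up": n_up,
             "n_down": n_down, "n_class": n, "defined": True}
        )
    return pd.DataFrame(rows).set_index("class")


# ---------------------------------------------------------------------------
# Pathway over-representation

def read_gmt(path: str | Path) -> dict[str, dict]:
    """Parse a GMT file: ``pathway_id <tab> description <tab> member...`` per line."""
    pathways: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need >= 3 fields): {line[:80]!r}")
        pid, desc, *members = parts
        pathways[pid] = {"description": desc, "members": set(members)}
    return pathways


def enrich(
    hits: Iterable[str],
    universe: Iterable[str],
    pathways: Mapping[str, Mapping],
    min_size: int = 2,
    q_thresh: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per pathway.

    Pathway members outside the universe are dropped with a warning.
    Pathways smaller than ``min_size`` (after restriction to the
    universe) are not tested.  P-values are BH-adjusted across the tested
    pathways.  The p-value is P[overlap >= observed] under sampling
    ``len(hits)`` features from the universe without replacement.
    """
    hits = set(hits)
    universe = set(universe)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    n_universe = len(universe)
    n_hits = len(hits)
    rows = []
    for pid, info in pathways.items():
        members = set(info["members"])
        outside = members - universe
        if outside:
            warnings.warn(
                f"pathway {pid!r}: {len(outside)} members outside universe dropped",
                stacklevel=2,
            )
        members &= universe
        size = len(members)
        if size < min_size:
            continue
        overlap = len(members & hits)
        # P[X >= overlap], X ~ Hypergeom(N=universe, K=size, n=hits)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, size, n_hits))
        rows.append(
            {"pathway_id": pid, "description": info.get("description", ""),
             "overlap": overlap, "pathway_size": size, "hits": n_hits,
             "universe": n_universe, "p": min(p, 1.0)}
        )
    result = pd.DataFrame(
        rows, columns=["pathway_id", "description", "overlap", "pathway_size",
                       "hits", "universe", "p"]
    )
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["q"] < q_thresh
        result = result.sort_values("p", kind="stable")
    else:
        result["q"] = []
        result["significant"] = []
    return result.set_index("pathway_id")
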