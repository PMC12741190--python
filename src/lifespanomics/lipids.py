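"""Lipid shorthand parsing and chain-length / saturation analytics.

Lipid species are named in the shorthand ``CLASS(C1:D1/.../Cn:Dn)`` —
class code followed by per-chain carbon:double-bond pairs, e.g.
``TG(16:0/18:1/18:2)``.  Sphingoid bases may carry a ``d`` (dihydroxy) or
``t`` (trihydroxy) prefix, as in ``SPH(d18:0)``; the prefix is parsed and
recorded but does not change carbon counting.

Saturation classes follow the convention: saturated (S) = 0 double
bonds, monounsaturated (MU) = exactly 1, polyunsaturated (PU) = 2 or
more.  By default a species is classified by its TOTAL double-bond
count; a per-chain mode is available for chain-resolved summaries, where
each chain is classified by its own double-bond count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_tables import FeatureTable, SampleMeta, LIFE_STAGE_GROUPS

__all__ = [
    "LIPID_CLASSES",
    "LipidAnnotation",
    "LipidParseError",
    "parse_lipid_name",
    "format_lipid_name",
    "annotate_features",
    "annotation_frame",
    "chain_saturation_matrix",
    "pu_s_ratio",
]

#: The 27 lipid class codes covered by the default grid (triglycerides,
#: phospholipids, sphingolipids, sterols, fatty acids and derivatives).
LIPID_CLASSES = (
    "Cer", "CerGGNAc", "CL", "Co", "DG", "FA", "FE", "GSLs", "Hex1SPH",
    "HexCer", "LPC", "LPE", "LPG", "LPI", "LSM", "MG", "PA", "PC", "PE",
    "PG", "PI", "PS", "SGalCer", "SM", "SPH", "ST", "TG",
)

_NAME_RE = re.compile(
    r"^\s*(?P<cls>[A-Za-z][A-Za-z0-9]*)\s*\(\s*(?P<chains>[^()]+?)\s*\)\s*$"
)
_CHAIN_RE = re.compile(r"^(?P<prefix>[dt]?)(?P<c>\d+):(?P<d>\d+)$")


class LipidParseError(ValueError):
    """Raised when a lipid shorthand name cannot be parsed."""


@dataclass(frozen=True)
class LipidAnnotation:
    """Parsed lipid species: class, per-chain composition, saturation class."""

    feature_id: str
    lipid_class: str
    chains: tuple[tuple[int, int], ...]  # (carbons, double bonds) per chain
    sphingoid_prefix: str = ""  # "d"/"t" prefix of the first chain, if any

    @property
    def total_carbons(self) -> int:
        return sum(c for c, _ in self.chains)

    @property
    def total_db(self) -> int:
        return sum(d for _, d in self.chains)

    @property
    def saturation(self) -> str:
        return classify_saturation(self.total_db)


def classify_saturation(n_double_bonds: int) -> str:
    """S for 0 double bonds, MU for exactly 1, PU for 2 or more."""
    if n_double_bonds < 0:
        raise LipidParseError(f"negative double-bond count: {n_double_bonds}")
    if n_double_bonds == 0:
        return "S"
    if n_double_bonds == 1:
        return "MU"
    return "PU"


def parse_lipid_name(name: str) -> LipidAnnotation:
    """Parse ``CLASS(C1:D1/.../Cn:Dn)`` shorthand into a :class:`LipidAnnotation`.

    Whitespace around the class code and inside the parentheses is
    tolerated.  Unparseable names raise :class:`LipidParseError` naming
    the offending part.
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise LipidParseError(f"unparseable lipid name: {name!r}")
    cls = m.group("cls")
    chains: list[tuple[int, int]] = []
    prefix = ""
    parts = [p.strip() for p in m.group("chains").split("/")]
    for i, part in enumerate(parts):
        cm = _CHAIN_RE.match(part)
        if cm is None:
            raise LipidParseError(f"unparseable chain {part!r} in {name!r}")
        if cm.group("prefix"):
            if i == 0:
                prefix = cm.group("prefix")
            # non-leading prefixes are tolerated but not recorded
        chains.append((int(cm.group("c")), int(cm.group("d"))))
    return LipidAnnotation(
        feature_id=name.strip(), lipid_class=cls, chains=tuple(chains),
        sphingoid_prefix=prefix,
    )


def format_lipid_name(ann: LipidAnnotation) -> str:
    """Canonical shorthand for an annotation (inverse of :func:`parse_lipid_name`)."""
    parts = []
    for i, (c, d) in enumerate(ann.chains):
        pre = ann.sphingoid_prefix if i == 0 else ""
        parts.append(f"{pre}{c}:{d}")
    return f"{ann.lipid_class}({'/'.join(parts)})"


def annotate_features(feature_ids: Iterable[str]) -> list[LipidAnnotation]:
    """Parse every feature id; failures propagate with the offending name."""
    return [parse_lipid_name(f) for f in feature_ids]


def annotation_frame(annotations: Sequence[LipidAnnotation]) -> pd.DataFrame:
    """Tabular export of annotations (one row per species)."""
    return pd.DataFrame(
        {
            "feature_id": [a.feature_id for a in annotations],
            "lipid_class": [a.lipid_class for a in annotations],
            "chains": ["/".join(f"{c}:{d}" for c, d in a.chains) for a in annotations],
            "total_carbons": [a.total_carbons for a in annotations],
            "total_db": [a.total_db for a in annotations],
            "saturation": [a.saturation for a in annotations],
        }
    ).set_index("feature_id")


def chain_saturation_matrix(
    t: FeatureTable,
    annotations: Sequence[LipidAnnotation],
    lipid_class: str,
    m: SampleMeta,
    group: str,
    per_chain: bool = True,
) -> pd.DataFrame:
    """Summed group intensity over (chain length x saturation class) cells.

    For every species of ``lipid_class``, intensities of the group's
    samples are summed into cells indexed by carbon chain length (rows)
    and saturation class S/MU/PU (columns).

    With ``per_chain=True`` (default) a species contributes once per
    DISTINCT chain length it contains, and the cell's saturation class is
    that chain's own double-bond count — chain-resolved summaries.  With
    ``per_chain=False`` the species contributes once, at its total carbon
    count, classified by its total double bonds.
    """
    m = m.aligned_to(t)
    members = [a for a in annotations if a.lipid_class == lipid_class]
    if not members:
        import warnings

        warnings.warn(f"no species of class {lipid_class!r}", stacklevel=2)
        return pd.DataFrame(columns=["S", "MU", "PU"], dtype=float)
    samples = m.samples_in_group(group)
    totals: dict[tuple[int, str], float] = {}
    for a in members:
        if a.feature_id not in t.data.index:
            continue
        intensity = float(t.data.loc[a.feature_id, samples].sum())
        if per_chain:
            seen: set[int] = set()
            for carbons, db in a.chains:
                if carbons in seen:
                    continue  # one contribution per distinct chain length
                seen.add(carbons)
                key = (carbons, classify_saturation(db))
                totals[key] = totals.get(key, 0.0) + intensity
        else:
            key = (a.total_carbons, a.saturation)
            totals[key] = totals.get(key, 0.0) + intensity
    lengths = sorted({k[0] for k in totals})
    mat = pd.DataFrame(0.0, index=lengths, columns=["S", "MU", "PU"])
    for (length, sat), v in totals.items():
        mat.loc[length, sat] = v
    mat.index.name = "chain_length"
    return mat


def pu_s_ratio(
    t: FeatureTable,
    annotations: Sequence[LipidAnnotation],
    m: SampleMeta,
    exclude_classes: Iterable[str] = (),
) -> pd.DataFrame:
    """Polyunsaturated : saturated intensity ratio per life-stage group.

    The ratio is computed per sample (sum of PU-species intensities over
    sum of S-species intensities, total-double-bond classification) and
    then averaged within each group; the per-sample form makes the group
    summary robust to unequal group sizes and matches mean +/- SEM
    reporting over biological replicates.  Samples with zero saturated
    total are flagged (ratio = inf) and excluded from the group mean with
    a count in the output.

    Returns a DataFrame indexed by group with columns ``ratio_mean``,
    ``ratio_sem``, ``n`` and ``n_undefined``.
    """
    exclude = set(exclude_classes)
    kept = [a for a in annotations if a.lipid_class not in exclude]
    if not kept:
        raise LipidParseError("exclude_classes removes every lipid class")
    m = m.aligned_to(t)
    pu_ids = [a.feature_id for a in kept if a.saturation == "PU" and a.feature_id in t.data.index]
    s_ids = [a.feature_id for a in kept if a.saturation == "S" and a.feature_id in t.data.index]
    pu_total = t.data.loc[pu_ids].sum(axis=0) if pu_ids else pd.Series(0.0, index=t.sample_ids)
    s_total = t.data.loc[s_ids].sum(axis=0) if s_ids else pd.Series(0.0, index=t.sample_ids)
    with np.errstate(divide="ignore"):
        per_sample = pu_total / s_total
    rows = []
    for g in LIFE_STAGE_GROUPS:
        samples = m.samples_in_group(g)
        if not samples:
            continue
        vals = per_sample[samples]
        finite = vals[np.isfinite(vals)]
        rows.append(
            {
                "group": g,
                "ratio_mean": float(finite.mean()) if len(finite) else np.nan,
                "ratio_sem": float(finite.std(ddof=1) / np.sqrt(len(finite)))
                if len(finite) > 1
                else np.nan,
                "n": int(len(finite)),
                "n_undefined": int((~np.isfinite(vals)).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("group")
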