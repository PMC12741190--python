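"""Feature abundance tables, sample metadata, normalization and filtering.

The central container is :class:`FeatureTable`: a nonnegative abundance
matrix (rows = features, columns = samples) with a modality tag
(``metabolite`` or ``lipid``) and a normalization state.  Sample-level
annotations (age in years, sex, life-stage group) live in
:class:`SampleMeta`.  All downstream stages — differential profiling,
trajectory modelling, clocks — consume these two objects.

Normalization follows standard untargeted-metabolomics practice: total-sum
normalization (each sample column divided by its sum) as the primary
method, and median-ratio normalization (each column divided by its median)
as a robustness check.  Zeros are preserved through normalization; log
transforms downstream add a small offset instead of a pseudo-count here,
which keeps normalization linear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LIFE_STAGE_GROUPS",
    "DEFAULT_GROUP_BOUNDARIES",
    "FeatureTable",
    "SampleMeta",
    "FeatureTableError",
    "read_feature_table",
    "write_feature_table",
    "total_sum_normalize",
    "median_ratio_normalize",
    "filter_nonzero_by_group",
    "compute_qc_cv",
    "filter_by_qc_cv",
    "batch_correction_hook",
    "assign_group",
    "log_offset",
    "log_transform",
]

#: Ordered life-stage labels, newborn through late adulthood.
LIFE_STAGE_GROUPS = (
    "A_newborn",
    "B_early_childhood",
    "C_middle_childhood",
    "D_adolescence",
    "E_early_adulthood",
    "F_middle_adulthood",
    "G_late_adulthood",
)

#: Default age boundaries in years, as half-open intervals [lo, hi).
#: Newborns are cord-blood samples at age exactly 0.  The elderly cut-off
#: (>= 65) and young cut-off (< 40) align with the elderly-vs-young
#: classification task downstream.
DEFAULT_GROUP_BOUNDARIES: Mapping[str, tuple[float, float]] = {
    "A_newborn": (0.0, 0.0),
    "B_early_childhood": (0.0, 6.0),
    "C_middle_childhood": (6.0, 12.0),
    "D_adolescence": (12.0, 19.0),
    "E_early_adulthood": (19.0, 40.0),
    "F_middle_adulthood": (40.0, 65.0),
    "G_late_adulthood": (65.0, 120.0),
}

VALID_MODALITIES = ("metabolite", "lipid")
VALID_STATES = ("raw", "total_sum", "median_ratio")


class FeatureTableError(ValueError):
    """Raised on invalid feature tables or metadata."""


def assign_group(age: float, boundaries: Mapping[str, tuple[float, float]] | None = None) -> str:
    """Map an age in years to its life-stage group label.

    Age 0 is the newborn (cord-blood) group; other ages fall into
    half-open ``[lo, hi)`` intervals except early childhood, which is
    open at 0 because age 0 is claimed by newborns.
    """
    bounds = boundaries or DEFAULT_GROUP_BOUNDARIES
    if age < 0:
        raise FeatureTableError(f"negative age: {age}")
    if age == bounds["A_newborn"][0]:
        return "A_newborn"
    for group in LIFE_STAGE_GROUPS[1:]:
        lo, hi = bounds[group]
        if lo <= age < hi:
            return group
    raise FeatureTableError(f"age {age} outside configured group boundaries")


@dataclass
class FeatureTable:
    """Abundance matrix with feature/sample identifiers and state tags.

    Parameters
    ----------
    data : pandas.DataFrame
        Nonnegative abundances; index = feature ids, columns = sample ids.
    modality : str
        ``"metabolite"`` or ``"lipid"``.
    normalization_state : str
        ``"raw"``, ``"total_sum"`` or ``"median_ratio"``.
    """

    data: pd.DataFrame
    modality: str = "metabolite"
    normalization_state: str = "raw"

    def __post_init__(self) -> None:
        if self.modality not in VALID_MODALITIES:
            raise FeatureTableError(f"unknown modality {self.modality!r}")
        if self.normalization_state not in VALID_STATES:
            raise FeatureTableError(
                f"unknown normalization state {self.normalization_state!r}"
            )
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate feature ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise FeatureTableError("non-finite abundance values")
        if (values < 0).any():
            raise FeatureTableError("negative abundance values")
        self.data = self.data.astype(float)
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        keep = [f for f in feature_ids]
        return replace(self, data=self.data.loc[keep])

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        keep = [s for s in sample_ids]
        return replace(self, data=self.data[keep])

    def copy(self) -> "FeatureTable":
        return replace(self, data=self.data.copy())


@dataclass
class SampleMeta:
    """Per-sample age (years), sex ({F, M}) and life-stage group."""

    table: pd.DataFrame
    boundaries: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_BOUNDARIES)
    )

    def __post_init__(self) -> None:
        required = {"age", "sex", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise FeatureTableError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate sample ids in metadata: {dups}")
        if (self.table["age"] < 0).any():
            raise FeatureTableError("negative ages in metadata")
        bad_sex = set(self.table["sex"]) - {"F", "M"}
        if bad_sex:
            raise FeatureTableError(f"invalid sex labels: {sorted(bad_sex)}")
        bad_group = set(self.table["group"]) - set(LIFE_STAGE_GROUPS)
        if bad_group:
            raise FeatureTableError(f"invalid group labels: {sorted(bad_group)}")
        self.table = self.table.copy()
        self.table["group"] = pd.Categorical(
            self.table["group"], categories=list(LIFE_STAGE_GROUPS), ordered=True
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def age(self) -> pd.Series:
        return self.table["age"]

    @property
    def sex(self) -> pd.Series:
        return self.table["sex"]

    @property
    def group(self) -> pd.Series:
        return self.table["group"]

    def samples_in_group(self, group: str) -> list[str]:
        if group not in LIFE_STAGE_GROUPS:
            raise FeatureTableError(f"unknown group {group!r}")
        return list(self.table.index[self.table["group"] == group])

    def aligned_to(self, t: FeatureTable) -> "SampleMeta":
        """Reorder metadata rows to a table's sample order, validating coverage."""
        missing = set(t.sample_ids) - set(self.table.index)
        if missing:
            raise FeatureTableError(
                f"metadata missing samples: {sorted(missing)}"
            )
        return SampleMeta(self.table.loc[t.sample_ids], boundaries=self.boundaries)


# ---------------------------------------------------------------------------
# I/O

def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_feature_table(
    path: str | Path,
    meta_path: str | Path,
    modality: str = "metabolite",
) -> tuple[FeatureTable, SampleMeta]:
    """Read an abundance matrix and its sample metadata from delimited text.

    The matrix has features as rows, a header row of sample ids, and a
    numeric body.  Metadata columns: ``sample_id, age, sex, group``.
    Sample sets must match exactly; parsing failures name the offending
    cell or id.
    """
    raw = _read_delimited(path)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        rows, cols = np.where(numeric.isna().to_numpy())
        r, c = rows[0], cols[0]
        raise FeatureTableError(
            f"non-numeric cell at feature {raw.index[r]!r}, sample {raw.columns[c]!r}: "
            f"{raw.iloc[r, c]!r}"
        )
    meta_raw = _read_delimited(meta_path)
    meta = SampleMeta(meta_raw)
    missing_in_meta = set(numeric.columns) - set(meta.sample_ids)
    missing_in_table = set(meta.sample_ids) - set(numeric.columns)
    if missing_in_meta or missing_in_table:
        raise FeatureTableError(
            "sample sets differ between table and metadata; "
            f"missing from metadata: {sorted(missing_in_meta)}; "
            f"missing from table: {sorted(missing_in_table)}"
        )
    table = FeatureTable(numeric, modality=modality, normalization_state="raw")
    return table, meta.aligned_to(table)


def write_feature_table(
    t: FeatureTable, path: str | Path, meta: SampleMeta | None = None,
    meta_path: str | Path | None = None,
) -> None:
    """Write a table (and optionally metadata) as delimited text.

    Numbers are written with ``repr`` round-trip precision so a
    write→read cycle reproduces values exactly.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    t.data.to_csv(path, sep=sep, index_label="feature_id")
    if meta is not None:
        if meta_path is None:
            raise FeatureTableError("meta_path required when writing metadata")
        meta_path = Path(meta_path)
        msep = "\t" if meta_path.suffix.lower() in {".tsv", ".txt"} else ","
        out = meta.table.copy()
        out["group"] = out["group"].astype(str)
        out.to_csv(meta_path, sep=msep, index_label="sample_id")


# ---------------------------------------------------------------------------
# Normalization

def total_sum_normalize(t: FeatureTable) -> FeatureTable:
    """Divide each sample column by its total, so every column sums to 1.

    Idempotent: re-applying to an already total-sum-normalized table is a
    no-op up to floating point.  Raises if any sample column is all zero.
    """
    if t.normalization_state == "median_ratio":
        raise FeatureTableError("table already median-ratio normalized")
    sums = t.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise FeatureTableError(
            f"all-zero sample columns: {list(zero.index)}"
        )
    return FeatureTable(t.data / sums, modality=t.modality,
                        normalization_state="total_sum")


def median_ratio_normalize(t: FeatureTable) -> FeatureTable:
    """Divide each sample column by its median abundance.

    The median is taken over all values of the sample, zeros included;
    when that median is 0 (heavily zero-inflated samples) the median of
    the nonzero values is used instead.  Raises when a sample has no
    positive values at all.
    """
    if t.normalization_state != "raw":
        raise FeatureTableError(
            f"median-ratio normalization requires raw input, got "
            f"{t.normalization_state!r}"
        )
    scales = {}
    for s in t.sample_ids:
        col = t.data[s].to_numpy()
        med = float(np.median(col))
        if med == 0.0:
            nz = col[col > 0]
            if nz.size == 0:
                raise FeatureTableError(f"sample {s!r} has zero median and no nonzero values")
            med = float(np.median(nz))
        scales[s] = med
    return FeatureTable(t.data / pd.Series(scales), modality=t.modality,
                        normalization_state="median_ratio")


# ---------------------------------------------------------------------------
# Filtering

def filter_nonzero_by_group(
    t: FeatureTable, m: SampleMeta, min_frac: float = 0.5
) -> tuple[FeatureTable, pd.DataFrame]:
    """Keep features whose nonzero fraction exceeds ``min_frac`` in >= 1 group.

    The comparison is strict (``>``): a feature nonzero in exactly half
    the samples of every group is dropped.  Returns the filtered table and
    a drop report (``feature_id``, ``reason``).
    """
    if not (0 < min_frac <= 1):
        raise FeatureTableError(f"min_frac must be in (0, 1], got {min_frac}")
    m = m.aligned_to(t)
    keep_mask = np.zeros(t.n_features, dtype=bool)
    groups = [g for g in LIFE_STAGE_GROUPS if (m.group == g).any()]
    nonzero = t.data.to_numpy() > 0
    for g in groups:
        cols = (m.group == g).to_numpy()
        frac = nonzero[:, cols].mean(axis=1)
        keep_mask |= frac > min_frac
    dropped = [f for f, k in zip(t.feature_ids, keep_mask) if not k]
    report = pd.DataFrame(
        {"feature_id": dropped,
         "reason": [f"nonzero fraction <= {min_frac} in every group"] * len(dropped)}
    )
    kept = [f for f, k in zip(t.feature_ids, keep_mask) if k]
    if not kept:
        warnings.warn("nonzero filter removed every feature", stacklevel=2)
    return t.subset_features(kept), report


def compute_qc_cv(qc_table: pd.DataFrame) -> pd.DataFrame:
    """Per-feature coefficient of variation (sd/mean) over QC replicate columns.

    Features with zero mean are flagged undefined (``cv`` = NaN).
    Standard deviation uses the ddof=1 sample convention.
    """
    values = qc_table.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame({"feature_id": qc_table.index, "cv": cv}).set_index(
        "feature_id"
    )


def filter_by_qc_cv(
    t: FeatureTable, qc: pd.DataFrame, max_cv: float = 0.3
) -> tuple[FeatureTable, pd.DataFrame, float]:
    """Keep features whose QC coefficient of variation is strictly below ``max_cv``.

    ``qc`` is the output of :func:`compute_qc_cv` (index = feature id,
    column ``cv``).  Features with undefined CV are dropped and flagged.
    Returns (filtered table, drop report, retained proportion).
    """
    missing = set(t.feature_ids) - set(qc.index)
    if missing:
        raise FeatureTableError(f"QC profile missing features: {sorted(missing)[:5]}")
    cv = qc.loc[t.feature_ids, "cv"]
    keep = (cv < max_cv).fillna(False)
    dropped = cv.index[~keep]
    reasons = [
        "undefined cv (zero mean)" if np.isnan(cv[f]) else f"cv {cv[f]:.4g} >= {max_cv}"
        for f in dropped
    ]
    report = pd.DataFrame({"feature_id": list(dropped), "reason": reasons})
    retained = float(keep.mean()) if len(keep) else 0.0
    return t.subset_features(list(cv.index[keep])), report, retained


def batch_correction_hook(t: FeatureTable, **kwargs) -> FeatureTable:
    """No-op stand-in for QC-anchored batch correction.

    Batch correction (e.g. support-vector-regression against pooled QC
    injections) is an external step; this hook has the signature a
    corrected table would flow through, so callers can inject one.
    """
    return t


# ---------------------------------------------------------------------------
# Log transform helpers shared by the statistical stages

def log_offset(t: FeatureTable) -> float:
    """Offset added before log transforms: half the smallest positive value."""
    values = t.values
    positive = values[values > 0]
    if positive.size == 0:
        raise FeatureTableError("table has no positive values")
    return float(positive.min()) * 0.5


def log_transform(t: FeatureTable, base: float = 10.0, offset: float | None = None) -> pd.DataFrame:
    """``log_base(x + offset)`` of the abundance matrix, as a DataFrame."""
    if offset is None:
        offset = log_offset(t)
    return np.log(t.data + offset) / np.log(base)
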