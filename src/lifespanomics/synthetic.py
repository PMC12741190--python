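"""Synthetic lifespan cohort generator with known ground truth.

Emulates a cross-sectional plasma cohort: ~136 subjects aged 0–84 split
into seven life-stage groups (newborn through late adulthood), with
features following one of five log-scale age trajectories —

* ``null``       — flat (no age signal),
* ``linear``     — slope ``beta`` per year,
* ``peak``       — Gaussian bump centered at ``peak_age`` with sd ``peak_width``,
* ``step``       — shift of ``step_delta`` for ages >= ``step_age``,
* ``group_marker`` — shift of ``marker_delta`` in one life-stage group —

under multiplicative log-normal noise (``noise_sigma``), an optional
additive log-scale sex effect (applied to males), and zero-inflation.
Abundance is ``base_level * exp(trajectory(age) + sex_term + N(0, sigma))``
with zeros injected at the configured rate.

Every generated feature is recorded in a truth table with its kind and
parameters, so downstream stages can be validated by parameter recovery.
One global seed derives an independent substream per feature (and one for
the subjects), so adding features never perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_tables import (
    DEFAULT_GROUP_BOUNDARIES,
    LIFE_STAGE_GROUPS,
    FeatureTable,
    SampleMeta,
)
from .lipids import parse_lipid_name

__all__ = [
    "TrajectorySpec",
    "CohortConfig",
    "simulate_cohort",
    "simulate_lipid_panel",
    "default_specs",
    "default_lipid_grid",
]

_KINDS = ("null", "linear", "peak", "step", "group_marker")


@dataclass(frozen=True)
class TrajectorySpec:
    """Ground-truth age trajectory for a block of synthetic features.

    Exactly the parameters of ``kind`` are meaningful; ``n_features``
    replicates the archetype with independent noise streams.  All deltas
    and slopes are on the natural-log abundance scale.
    """

    kind: str
    n_features: int = 1
    beta: float = 0.0  # linear: log-abundance slope per year
    peak_age: float = 0.0  # peak: center (years)
    peak_width: float = 0.0  # peak: Gaussian sd (years)
    peak_height: float = 1.0  # peak: bump height (log scale)
    step_age: float = 0.0  # step: change point (years)
    step_delta: float = 0.0  # step: log-scale shift at/after step_age
    marker_group: str = ""  # group_marker: life-stage label
    marker_delta: float = 0.0  # group_marker: log-scale shift in that group
    sex_delta: float = 0.0  # log-scale shift applied to males
    base_level: float = 1000.0  # multiplicative scale (intensity units)
    prefix: str = ""  # feature-id prefix override

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.base_level <= 0:
            raise ValueError("base_level must be positive")
        if self.kind == "peak" and self.peak_width <= 0:
            raise ValueError("peak trajectories need peak_width > 0")
        if self.kind == "group_marker" and self.marker_group not in LIFE_STAGE_GROUPS:
            raise ValueError(f"unknown marker_group {self.marker_group!r}")

    def log_trajectory(self, age: np.ndarray, group: np.ndarray) -> np.ndarray:
        """Deterministic log-scale age component for an array of subjects."""
        age = np.asarray(age, dtype=float)
        if self.kind == "null":
            return np.zeros_like(age)
        if self.kind == "linear":
            return self.beta * age
        if self.kind == "peak":
            z = (age - self.peak_age) / self.peak_width
            return self.peak_height * np.exp(-0.5 * z * z)
        if self.kind == "step":
            return self.step_delta * (age >= self.step_age)
        # group_marker
        return self.marker_delta * (np.asarray(group) == self.marker_group)


#: Default per-group subject counts (sum 136): cord-blood newborns plus
#: six equal post-natal groups.
DEFAULT_GROUP_SIZES = {
    "A_newborn": 16,
    "B_early_childhood": 20,
    "C_middle_childhood": 20,
    "D_adolescence": 20,
    "E_early_adulthood": 20,
    "F_middle_adulthood": 20,
    "G_late_adulthood": 20,
}


@dataclass
class CohortConfig:
    """Cohort-level simulation settings.

    ``noise_sigma`` is the log-scale sd of the multiplicative noise
    (0.2 by default — mid-range biological CV for plasma features);
    ``zero_inflation`` is the per-cell missing-at-random zero rate.
    """

    n_subjects: int = 136
    age_range: tuple[float, float] = (0.0, 84.0)
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    noise_sigma: float = 0.2
    zero_inflation: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.group_sizes.values())
        if total != self.n_subjects:
            raise ValueError(
                f"group sizes sum to {total}, expected n_subjects = {self.n_subjects}"
            )
        unknown = set(self.group_sizes) - set(LIFE_STAGE_GROUPS)
        if unknown:
            raise ValueError(f"unknown groups in group_sizes: {sorted(unknown)}")
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _subject_stream(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(0,))))


def _feature_stream(seed: int, index: int) -> np.random.Generator:
    # spawn_key (1, index): independent of the subject stream and of every
    # other feature, so feature blocks can be added without reshuffling.
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(1, index)))
    )


def _draw_subjects(cfg: CohortConfig) -> pd.DataFrame:
    rng = _subject_stream(cfg.seed)
    rows = []
    i = 0
    for g in LIFE_STAGE_GROUPS:
        n = cfg.group_sizes.get(g, 0)
        lo, hi = DEFAULT_GROUP_BOUNDARIES[g]
        hi = min(hi, cfg.age_range[1])
        for _ in range(n):
            if g == "A_newborn":
                age = 0.0  # cord blood
            else:
                age = float(rng.uniform(lo, hi))
            sex = "M" if rng.random() < 0.5 else "F"
            rows.append({"sample_id": f"S{i:03d}", "age": age, "sex": sex, "group": g})
            i += 1
    return pd.DataFrame(rows).set_index("sample_id")


def _truth_row(fid: str, spec: TrajectorySpec) -> dict:
    return {
        "feature_id": fid,
        "kind": spec.kind,
        "beta": spec.beta,
        "peak_age": spec.peak_age,
        "peak_width": spec.peak_width,
        "peak_height": spec.peak_height,
        "step_age": spec.step_age,
        "step_delta": spec.step_delta,
        "marker_group": spec.marker_group,
        "marker_delta": spec.marker_delta,
        "sex_delta": spec.sex_delta,
        "base_level": spec.base_level,
    }


def simulate_cohort(
    cfg: CohortConfig,
    specs: Sequence[TrajectorySpec],
    modality: str = "metabolite",
    feature_names: Sequence[str] | None = None,
) -> tuple[FeatureTable, SampleMeta, pd.DataFrame]:
    """Simulate a cohort feature table, metadata and ground-truth table.

    ``feature_names`` overrides the auto-generated ids (it must then
    match the total expanded feature count); otherwise ids are
    ``{kind}_{i:04d}`` (or ``{prefix}{i:04d}`` when the spec sets one).
    Deterministic given ``cfg.seed``.
    """
    meta_df = _draw_subjects(cfg)
    age = meta_df["age"].to_numpy()
    group = meta_df["group"].to_numpy()
    male = (meta_df["sex"] == "M").to_numpy()

    expanded: list[TrajectorySpec] = []
    for spec in specs:
        expanded.extend([spec] * spec.n_features)
    if feature_names is not None and len(feature_names) != len(expanded):
        raise ValueError(
            f"feature_names has {len(feature_names)} entries, expected {len(expanded)}"
        )

    n_samples = len(meta_df)
    values = np.empty((len(expanded), n_samples))
    ids: list[str] = []
    truth_rows: list[dict] = []
    counter: dict[str, int] = {}
    for idx, spec in enumerate(expanded):
        if feature_names is not None:
            fid = str(feature_names[idx])
        else:
            key = spec.prefix or spec.kind
            counter[key] = counter.get(key, 0) + 1
            fid = f"{key}_{counter[key]:04d}"
        rng = _feature_stream(cfg.seed, idx)
        log_mu = (
            math.log(spec.base_level)
            + spec.log_trajectory(age, group)
            + spec.sex_delta * male
        )
        noise = rng.normal(0.0, cfg.noise_sigma, size=n_samples)
        row = np.exp(log_mu + noise)
        if cfg.zero_inflation > 0:
            row = np.where(rng.random(n_samples) < cfg.zero_inflation, 0.0, row)
        values[idx] = row
        ids.append(fid)
        truth_rows.append(_truth_row(fid, spec))

    data = pd.DataFrame(values, index=ids, columns=meta_df.index)
    table = FeatureTable(data, modality=modality, normalization_state="raw")
    truth = pd.DataFrame(truth_rows).set_index("feature_id")
    return table, SampleMeta(meta_df), truth


def default_specs(
    n_null: int = 200,
    n_linear: int = 60,
    n_peak: int = 30,
    n_step: int = 30,
    n_marker_per_group: int = 3,
) -> list[TrajectorySpec]:
    """Standard mixture of trajectory archetypes for a study-scale cohort.

    Linear slopes span +/-0.005 to +/-0.02 per year (0.5–2% yearly
    change), peaks crest at ages 10–60, steps switch at ages 10–65, and
    each life-stage group gets a few dedicated markers — the magnitudes a
    plasma cohort of this size can plausibly resolve.
    """
    specs: list[TrajectorySpec] = [TrajectorySpec("null", n_features=n_null)]
    slopes = [0.005, -0.005, 0.01, -0.01, 0.02, -0.02]
    per = max(n_linear // len(slopes), 1)
    for b in slopes:
        specs.append(TrajectorySpec("linear", n_features=per, beta=b, sex_delta=0.05))
    peaks = [(10, 5), (20, 6), (40, 8), (60, 8)]
    per = max(n_peak // len(peaks), 1)
    for age0, width in peaks:
        specs.append(
            TrajectorySpec("peak", n_features=per, peak_age=age0, peak_width=width,
                           peak_height=0.8)
        )
    steps = [(10, 0.5), (40, 0.5), (65, 0.6), (40, -0.5), (65, -0.6)]
    per = max(n_step // len(steps), 1)
    for age0, delta in steps:
        specs.append(TrajectorySpec("step", n_features=per, step_age=age0, step_delta=delta))
    for g in LIFE_STAGE_GROUPS:
        specs.append(
            TrajectorySpec(
                "group_marker", n_features=n_marker_per_group, marker_group=g,
                marker_delta=1.0, prefix=f"marker_{g}",
            )
        )
    return specs


def default_lipid_grid() -> list[str]:
    """Shorthand names spanning the 27 lipid classes with varied chains.

    Single-chain classes (sphingoid bases, fatty acids, lyso-species,
    monoglycerides, sterols) get one chain; glycerophospholipids and
    sphingolipids two; triglycerides three.  Chain lengths and
    double-bond counts cover S/MU/PU species in every class.
    """
    single = {"SPH", "Hex1SPH", "FA", "FE", "MG", "ST", "Co",
              "LPC", "LPE", "LPG", "LPI", "LSM"}
    triple = {"TG"}
    quad = {"CL"}
    grid: list[str] = []
    chain_opts = [(16, 0), (18, 0), (20, 0), (22, 0), (16, 1), (18, 1),
                  (18, 2), (20, 4), (22, 5), (22, 6)]
    for cls in (
        "Cer", "CerGGNAc", "CL", "Co", "DG", "FA", "FE", "GSLs", "Hex1SPH",
        "HexCer", "LPC", "LPE", "LPG", "LPI", "LSM", "MG", "PA", "PC", "PE",
        "PG", "PI", "PS", "SGalCer", "SM", "SPH", "ST", "TG",
    ):
        sph_like = cls in {"SPH", "Hex1SPH", "Cer", "HexCer", "SM", "LSM",
                           "SGalCer", "GSLs", "CerGGNAc"}
        prefix = "d" if sph_like else ""
        if cls in single:
            for c, d in chain_opts[:6] + chain_opts[6:8]:
                grid.append(f"{cls}({prefix}{c}:{d})")
        elif cls in triple:
            grid.append(f"{cls}(16:0/18:0/18:0)")
            grid.append(f"{cls}(16:0/18:1/18:2)")
            grid.append(f"{cls}(18:1/18:1/18:2)")
            grid.append(f"{cls}(16:0/18:1/16:0)")
            grid.append(f"{cls}(18:2/18:2/22:6)")
        elif cls in quad:
            grid.append(f"{cls}(18:2/18:2/18:2/18:2)")
            grid.append(f"{cls}(16:0/18:1/18:2/18:2)")
        else:
            for (c1, d1), (c2, d2) in [
                ((16, 0), (18, 0)), ((16, 0), (18, 1)), ((18, 0), (18, 1)),
                ((18, 0), (18, 2)), ((18, 1), (20, 4)), ((20, 0), (22, 5)),
                ((18, 2), (22, 6)),
            ]:
                grid.append(f"{cls}({prefix}{c1}:{d1}/{c2}:{d2})")
    return grid


def simulate_lipid_panel(
    cfg: CohortConfig,
    grid: Sequence[str] | None = None,
    sph_marker_delta: float = 1.0,
    pu_trend_beta: float = 0.01,
    specs_by_name: dict[str, TrajectorySpec] | None = None,
) -> tuple[FeatureTable, SampleMeta, pd.DataFrame]:
    """Simulate a lipid table whose feature ids are parseable shorthand.

    Every grid entry is validated by parsing.  Saturated SPH species get
    a newborn group-marker effect of ``sph_marker_delta`` (emulating the
    elevated saturated sphingoid bases of cord blood).  Polyunsaturated
    glycerolipid/phospholipid species carry balanced linear age trends of
    slope ``pu_trend_beta``: PU triglycerides and PE rise with age, PU PC
    and PI fall, so individual species trend (supporting correlation
    networks and lipid age models) while the aggregate PU:S ratio stays
    near-level across groups once SPH is excluded.  Everything else is
    null unless overridden via ``specs_by_name``.  The metadata and
    subject draw match :func:`simulate_cohort` for the same config.
    """
    names = list(grid) if grid is not None else default_lipid_grid()
    specs: list[TrajectorySpec] = []
    for name in names:
        ann = parse_lipid_name(name)  # raises naming the malformed entry
        if specs_by_name and name in specs_by_name:
            specs.append(specs_by_name[name])
        elif ann.lipid_class == "SPH" and ann.saturation == "S" and sph_marker_delta:
            specs.append(
                TrajectorySpec(
                    "group_marker", marker_group="A_newborn",
                    marker_delta=sph_marker_delta,
                )
            )
        elif ann.saturation == "PU" and pu_trend_beta and ann.lipid_class in (
            "TG", "PE",
        ):
            specs.append(TrajectorySpec("linear", beta=pu_trend_beta))
        elif ann.saturation == "PU" and pu_trend_beta and ann.lipid_class in (
            "PC", "PI",
        ):
            specs.append(TrajectorySpec("linear", beta=-pu_trend_beta))
        else:
            specs.append(TrajectorySpec("null"))
    return simulate_cohort(cfg, specs, modality="lipid", feature_names=names)
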