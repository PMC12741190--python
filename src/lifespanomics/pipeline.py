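"""End-to-end pipeline: configuration, stage orchestration, run manifest.

Stages run in dependency order — simulate (or load) → normalize/filter →
differential → trajectories → deswan → lipids → pvca → network → clock →
panel — each writing its outputs as delimited text with fixed 12
significant-digit formatting, so identical configurations and seeds
produce byte-identical output trees.  One global seed derives a per-stage
seed through a hash of the stage name, so toggling one stage never shifts
another stage's randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clock as clock_mod
from . import core_tables as ct
from . import differential as de_mod
from . import lipids as lipid_mod
from . import synthetic as syn
from . import trajectory as traj
from . import variance as var_mod

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger("lifespanomics")

STAGES = (
    "simulate", "normalize", "de", "trajectories", "deswan",
    "lipids", "pvca", "network", "clock", "panel",
)

#: Upstream stages each stage needs within one run.
STAGE_DEPS = {
    "simulate": (),
    "normalize": ("simulate",),
    "de": ("normalize",),
    "trajectories": ("normalize",),
    "deswan": ("normalize",),
    "lipids": ("normalize",),
    "pvca": ("normalize",),
    "network": ("trajectories",),
    "clock": ("normalize",),
    "panel": ("clock", "trajectories"),
}

_FLOAT_FMT = "%.12g"


class PipelineError(RuntimeError):
    """Stage failure or unmet stage dependency."""


@dataclass
class RunConfig:
    """Structured run configuration with the documented defaults.

    Thresholds: q (BH significance) 0.05, Spearman |rho| 0.5, QC CV 0.3,
    nonzero fraction 0.5, DE-SWAN window 20 years, k = 8 trajectory
    clusters, elderly/young age cut-offs 65/40 years.
    """

    outdir: str = "results"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # simulate block
    n_subjects: int = 136
    group_sizes: dict = field(default_factory=lambda: dict(syn.DEFAULT_GROUP_SIZES))
    noise_sigma: float = 0.2
    zero_inflation: float = 0.02
    n_null: int = 200
    n_linear: int = 60
    n_peak: int = 30
    n_step: int = 30
    n_marker_per_group: int = 3
    # thresholds
    q_thresh: float = 0.05
    rho_thresh: float = 0.5
    qc_cv_max: float = 0.3
    nonzero_min_frac: float = 0.5
    deswan_window: float = 20.0
    k_clusters: int = 8
    loess_span: float = 0.75
    alpha_grid: list = field(default_factory=lambda: [0.1, 0.3, 0.5, 0.7, 0.9])
    train_fractions: list = field(default_factory=lambda: [0.5, 0.6, 0.7, 0.8])
    elderly_age: float = 65.0
    young_age: float = 40.0
    top_n_network: int = 50
    reduce_max_features: int = 30

    def validate(self) -> None:
        for name, lo, hi in [
            ("q_thresh", 0, 1), ("rho_thresh", 0, 1), ("qc_cv_max", 0, np.inf),
            ("nonzero_min_frac", 0, 1), ("loess_span", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise PipelineError(f"{name} = {v} outside ({lo}, {hi}]")
        if self.deswan_window <= 0:
            raise PipelineError("deswan_window must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed from the global seed and a hash of the stage name."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31 - 1)


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages; return (and persist) the run manifest.

    Any stage error aborts with the stage name; the partial manifest is
    still written.  Every output file is listed in the manifest with its
    SHA-256 digest.
    """
    from . import __version__

    cfg.validate()
    enabled = [s for s in STAGES if cfg.stages.get(s, True)]
    for s in enabled:
        missing = [d for d in STAGE_DEPS[s] if d not in enabled]
        if missing:
            raise PipelineError(
                f"stage {s!r} requires stage(s) {missing} which are toggled off"
            )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "seed": cfg.seed, "stages": enabled,
        "outputs": {}, "defaults_fired": [],
    }
    ctx: dict = {}

    def record(stage: str, *paths: Path) -> None:
        manifest["outputs"].setdefault(stage, {})
        for p in paths:
            manifest["outputs"][stage][p.name] = _sha256(p)

    try:
        for stage in enabled:
            log.info("stage %s", stage)
            _STAGE_FUNCS[stage](cfg, ctx, outdir, record)
    except Exception as exc:
        manifest["error"] = f"stage failed: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise PipelineError(f"pipeline aborted in stage {stage!r}: {exc}") from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations

def _stage_simulate(cfg: RunConfig, ctx: dict, outdir: Path, record) -> None:
    ccfg = syn.CohortConfig(
        n_subjects=cfg.n_subjects, group_sizes=dict(cfg.group_sizes),
        noise_sigma=cfg.noise_sigma, zero_inflation=cfg.zero_inflation,
        seed=stage_seed(cfg.seed, "simulate"),
    )
    specs = syn.default_specs(
        n_null=cfg.n_null, n_linear=cfg.n_linear, n_peak=cfg.n_peak,
        n_step=cfg.n_step, n_marker_per_group=cfg.n_marker_per_group,
    )
    metab, meta, truth_m = syn.simulate_cohort(ccfg, specs, modality="metabolite")
    lipid, _, truth_l = syn.simulate_lipid_panel(ccfg)
    ctx.update(metab_raw=metab, lipid_raw=lipid, meta=meta,
               truth_metab=truth_m, truth_lipid=truth_l)
    paths = []
    for name, obj in [("metabolites_raw.tsv", metab), ("lipids_raw.tsv", lipid)]:
        p = outdir / name
        ct.write_feature_table(obj, p)
        paths.append(p)
    p_meta = outdir / "samples.tsv"
    ct.write_feature_table(metab, outdir / "metabolites_raw.tsv", meta, p_meta)
    for name, df in [("truth_metabolites.tsv", truth_m), ("truth_lipids.tsv", truth_l)]:
        p = outdir / name
        _write_tsv(df, p, index_label="feature_id")
        paths.append(p)
    record("simulate", *paths, p_meta)


def _stage_normalize(cfg: RunConfig, ctx: dict, outdir: Path, record) -> None:
    paths = []
    for key in ("metab", "lipid"):
        raw = ctx[f"{key}_raw"]
        filtered, report = ct.filter_nonzero_by_group(raw, ctx["meta"], cfg.nonzero_min_frac)
        norm = ct.total_sum_normalize(ct.batch_correction_hook(filtered))
        ctx[key] = norm
        p1 = outdir / f"{key}_normalized.tsv"
        ct.write_feature_table(norm, p1)
        p2 = outdir / f"{key}_dropped.tsv"
        report.to_csv(p2, sep="\t", index=False)
        paths += [p1, p2]
    record("normalize", *paths)


def _stage_de(cfg: RunConfig, ctx: dict, outdir: Path, record) -> None:
    comparisons, upset = de_mod.newborn_contrasts(ctx["metab"], ctx["meta"], cfg.q_thresh)
    paths = []
    for g, comp in comparisons.items():
        p = outdir / f"de_newborn_vs_{g}.tsv"
        _write_tsv(comp.table, p, index_label="feature_id")
        paths.append(p)
    p = outdir / "de_newborn_intersections.tsv"
    upset.to_csv(p, sep="\t", index=False)
    paths.append(p)
    markers = de_mod.group_markers(ctx["metab"], ctx["meta"], cfg.q_thresh)
    p = outdir / "group_markers.tsv"
    rows = [{"group": g, "feature_id": f} for g, fs in markers.items() for f in fs]
    pd.DataFrame(rows, columns=["group", "feature_id"]).to_csv(p, sep="\t", index=False)
    paths.append(p)
    ctx["newborn_de"] = comparisons
    record("de", *paths)


def _stage_trajectories(cfg: RunConfig, ctx: dict, outdir: Path, record) -> None:
    paths = []
    for key in ("metab", "lipid"):
        models = traj.fit_linear_age(ctx[key], ctx["meta"], q_thresh=cfg.q_thresh)
        ctx[f"{key}_age_models"] = models
        p = outdir / f"{key}_age_models.tsv"
        _write_tsv(models, p, index_label="feature_id")
        paths.append(p)
    loess = traj.fit_loess_trajectories(ctx["metab"], ctx["meta"], span=cfg.loess_span)
    ctx["metab_loess"] = loess
    p = outdir / "metab_loess_curves.tsv"
    _write_tsv(loess.curves, p, index_label="feature_id")
    paths.append(p)
    if len(loess.standardized) >= cfg.k_clusters:
        clusters = traj.cluster_trajectories(loess.standardized, k=cfg.k_clusters)
        rows = [{"feature_id": f, "cluster": c.cluster_id}
                for c in clusters for f in c.member_features]
        p = outdir / "metab_trajectory_clusters.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        paths.append(p)
        ctx["metab_clusters"] = clusters
    record("trajectories", *paths)


def _stage_deswan(cfg: RunConfig, ctx: dict, outdir: Path, record) -> None:
    paths = []
    for key in ("metab", "lipid"):
        curve = traj.deswan(ctx[key], ctx["meta"], window=cfg.deswan_window,
                            q_thresh=cfg.q_thresh)
        ctx[f"{key}_deswan"] = curve
        p = outdir / f"{key}_deswan.tsv"
        _write_tsv(curve.to_frame(), p)
        paths.append(p)
    record("deswan", *paths)


def _stage_lipids(cfg: RunConfig, ctx: dict, outdir: Path, record) -> None:
    ann = lipid_mod.annotate_features(ctx["lipid"].feature_ids)
    paths = []
    p = outdir / "lipid_annotations.tsv"
    _write_tsv(lipid_mod.annotation_frame(ann), p)
    paths.append(p)
    ratios = lipid_mod.pu_s_ratio(ctx["lipid"], ann, ctx["meta"])
    p = outdir / "pu_s_ratio.tsv"
    _write_tsv(ratios, p)
    paths.append(p)
    ratios_nosph = lipid_mod.pu_s_ratio(ctx["lipid"], ann, ctx["meta"],
                                        exclude_classes={"SPH"})
    p = outdir / "pu_s_ratio_no_sph.tsv"
    _write_tsv(ratios_nosph, p)
    paths.append(p)
    ctx["lipid_annotations"] = ann
    record("lipids", *paths)


def _stage_pvca(cfg: RunConfig, ctx: dict, outdir: Path, record) -> None:
    paths = []
    for key in ("metab", "lipid"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = var_mod.pvca(ctx[key], ctx["meta"])
        p = outdir / f"{key}_pvca.tsv"
        _write_tsv(res.fractions.to_frame("fraction"), p, index_label="factor")
        paths.append(p)
        ctx[f"{key}_pvca"] = res
    record("pvca", *paths)


def _stage_network(cfg: RunConfig, ctx: dict, outdir: Path, record) -> None:
    edges = var_mod.spearman_network(
        ctx["metab"], ctx["lipid"], ctx["metab_age_models"], ctx["lipid_age_models"],
        top_n=cfg.top_n_network, rho_thresh=cfg.rho_thresh, q_thresh=cfg.q_thresh,
    )
    p1 = outdir / "network_edges.tsv"
    edges.to_csv(p1, sep="\t", index=False, float_format=_FLOAT_FMT)
    p2 = outdir / "network.graphml"
    var_mod.network_to_graphml(edges, p2)
    ctx["network"] = edges
    record("network", p1, p2)


def _stage_clock(cfg: RunConfig, ctx: dict, outdir: Path, record) -> None:
    seed = stage_seed(cfg.seed, "clock")
    model = clock_mod.fit_clock(
        [ctx["metab"], ctx["lipid"]], ctx["meta"],
        alpha_grid=tuple(cfg.alpha_grid), train_fractions=tuple(cfg.train_fractions),
        seed=seed,
    )
    ctx["clock"] = model
    p1 = outdir / "clock_model.json"
    nz = model.coefficients[model.coefficients != 0]
    p1.write_text(json.dumps({
        "alpha": model.alpha, "lambda": model.lam,
        "train_fraction": model.train_fraction,
        "mae_test": model.mae_test, "r_test": model.r_test,
        "intercept": model.intercept,
        "coefficients": {f: float(c) for f, c in nz.items()},
        "scaler_mean": {f: float(model.scaler_mean[f]) for f in nz.index},
        "scaler_scale": {f: float(model.scaler_scale[f]) for f in nz.index},
        "modality": {f: model.modality[f] for f in nz.index},
    }, indent=2, sort_keys=True))
    p2 = outdir / "clock_predictions.tsv"
    _write_tsv(model.predictions, p2, index_label="sample_id")
    reduced = clock_mod.reduce_clock(
        model, [ctx["metab"], ctx["lipid"]], ctx["meta"],
        alpha_grid=tuple(cfg.alpha_grid), seed=seed,
        max_features=cfg.reduce_max_features,
    )
    ctx["reduced_clock"] = reduced
    p3 = outdir / "reduced_clock_curve.tsv"
    _write_tsv(reduced.accuracy_curve, p3, index_label="n_features")
    p4 = outdir / "reduced_clock.json"
    p4.write_text(json.dumps({
        "breakpoint": reduced.breakpoint, "knot": reduced.knot,
        "low_confidence": reduced.low_confidence,
        "features": reduced.ranked_features[: reduced.breakpoint],
        "mae_test": reduced.final_model.mae_test,
        "r_test": reduced.final_model.r_test,
    }, indent=2, sort_keys=True))
    record("clock", p1, p2, p3, p4)


def _stage_panel(cfg: RunConfig, ctx: dict, outdir: Path, record) -> None:
    meta = ctx["meta"]
    ages = meta.table["age"]
    elderly_ids = list(ages.index[ages >= cfg.elderly_age])
    young_ids = list(ages.index[ages < cfg.young_age])
    combined_models = pd.concat([ctx["metab_age_models"], ctx["lipid_age_models"]])
    design, _ = clock_mod.clock_design([ctx["metab"], ctx["lipid"]])
    # elderly-vs-young DE on the combined feature set
    both = pd.concat([ctx["metab"].data, ctx["lipid"].data])
    combined_table = ct.FeatureTable(both, modality="metabolite",
                                     normalization_state="total_sum")
    de_elderly = de_mod.de_two_groups(
        combined_table, meta, elderly_ids, young_ids, q_thresh=cfg.q_thresh
    )
    selection = clock_mod.select_panel(de_elderly, combined_models, ctx["clock"],
                                       q_thresh=cfg.q_thresh)
    ctx["panel_selection"] = selection
    p1 = outdir / "panel_selection.json"
    p1.write_text(json.dumps({
        "elderly_up": sorted(selection.elderly_up),
        "age_increasing": sorted(selection.age_increasing),
        "clock_selected": sorted(selection.clock_selected),
        "intersection": selection.intersection,
        "pairwise_counts": selection.pairwise_counts,
    }, indent=2, sort_keys=True))
    paths = [p1]
    if len(selection.intersection) >= 2:
        panel = clock_mod.fit_panel_classifier(
            selection.intersection, [ctx["metab"], ctx["lipid"]], meta,
            seed=stage_seed(cfg.seed, "panel"),
            elderly_age=cfg.elderly_age, young_age=cfg.young_age,
        )
        ctx["panel"] = panel
        p2 = outdir / "panel_roc.tsv"
        panel.roc_points.to_csv(p2, sep="\t", index=False, float_format=_FLOAT_FMT)
        p3 = outdir / "panel_result.json"
        p3.write_text(json.dumps({
            "features": panel.selected_features,
            "cv_auc_mean": panel.cv_auc_mean,
            "fold_aucs": panel.fold_aucs,
            "coefficients": {f: float(c) for f, c in panel.coefficients.items()},
        }, indent=2, sort_keys=True))
        paths += [p2, p3]
    record("panel", *paths)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "de": _stage_de,
    "trajectories": _stage_trajectories,
    "deswan": _stage_deswan,
    "lipids": _stage_lipids,
    "pvca": _stage_pvca,
    "network": _stage_network,
    "clock": _stage_clock,
    "panel": _stage_panel,
}
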