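"""End-to-end orchestration: annotate → quantify → classify → dynamics → report.

Stages run deterministically from a :class:`RunConfig` (paths, thresholds,
tree roles, seed).  Every run writes a manifest recording the config hash
and the filter-cascade bookkeeping — samples per tree per phase and
compound counts surviving each DF threshold — so the cascade can be audited
against brute-force recounts of the raw tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, classify, dynamics, quantify, study
from .classify import (
    POST_PHASES,
    PRE_PHASES,
    EmissionContext,
    TreeRoles,
    classification_to_frame,
    classify_all,
)
from .study import DEFAULT_PHASES, PhaseDefinition

log = logging.getLogger("trunkvoc")

__all__ = ["Thresholds", "RunConfig", "run_pipeline", "make_report", "load_config"]


@dataclass(frozen=True)
class Thresholds:
    retention_df: float = 10.0
    constitutive_df: float = 50.0
    mean_inclusion_df: float = 20.0
    fold_change: float = 2.0
    comparability_band: float = 2.0
    tau_min: float = 0.5
    alpha: float = 0.05
    background_factor: float = 2.0
    lri_tolerance: float = 15.0

    def __post_init__(self) -> None:
        for name in ("retention_df", "constitutive_df", "mean_inclusion_df"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100]")
        for name in ("fold_change", "comparability_band", "background_factor",
                     "lri_tolerance"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class RunConfig:
    """All inputs, thresholds and options of one pipeline run."""

    design: str
    peaks: str
    alkanes: str
    library: str
    calibration: str
    surrogates: str = ""
    roles: TreeRoles = field(default_factory=TreeRoles)
    thresholds: Thresholds = field(default_factory=Thresholds)
    phases: tuple = DEFAULT_PHASES
    seed: int = 0
    out_dir: str = "results/run"
    pooled_constitutive: bool = False

    def canonical(self) -> str:
        """Stable textual form used for the config hash."""
        d = {
            "design": str(self.design),
            "peaks": str(self.peaks),
            "alkanes": str(self.alkanes),
            "library": str(self.library),
            "calibration": str(self.calibration),
            "surrogates": str(self.surrogates),
            "roles": asdict(self.roles),
            "thresholds": asdict(self.thresholds),
            "phases": [[p.phase_id, p.label, p.day_start, p.day_end] for p in self.phases],
            "seed": self.seed,
            "pooled_constitutive": self.pooled_constitutive,
        }
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read a run config from a YAML file (key–value, nested sections)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    inputs = raw.get("inputs", {})
    phases_raw = raw.get("phases")
    if phases_raw:
        labels = {1: "acclimation", 2: "abiotic_stress", 3: "biotic_stress"}
        phases = tuple(
            PhaseDefinition(i + 1, labels.get(i + 1, f"phase{i + 1}"), int(lo), int(hi))
            for i, (lo, hi) in enumerate(phases_raw)
        )
    else:
        phases = DEFAULT_PHASES
    return RunConfig(
        design=inputs["design"],
        peaks=inputs["peaks"],
        alkanes=inputs["alkanes"],
        library=inputs["library"],
        calibration=inputs["calibration"],
        surrogates=inputs.get("surrogates", ""),
        roles=TreeRoles(**raw.get("roles", {})),
        thresholds=Thresholds(**raw.get("thresholds", {})),
        phases=phases,
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "results/run")),
        pooled_constitutive=bool(raw.get("pooled_constitutive", False)),
    )


def _annotate_stage(cfg: RunConfig, obs_frame: pd.DataFrame) -> pd.DataFrame:
    ladder = annotation.load_ladder(cfg.alkanes)
    library = annotation.load_library(cfg.library)
    annotations = annotation.annotate_features(
        obs_frame, ladder, library, tolerance=cfg.thresholds.lri_tolerance
    )
    n_matched = int((annotations["best_match"] != "").sum())
    log.info("annotate: %d features, %d matched", len(annotations), n_matched)
    return annotations


def _dynamics_stage(
    cfg: RunConfig,
    ctx: EmissionContext,
    results,
    out: dict[str, pd.DataFrame],
    class_of: dict[str, str] | None = None,
) -> None:
    roles = cfg.roles
    home_tree = {
        "hipv": roles.infested,
        "stress_induced": roles.infested,
        "neighbor_induced": roles.neighbor,
        "constitutive": roles.infested,
    }
    fit_rows = []
    series: dict[str, pd.Series] = {}
    fitted = [
        r for r in results if r.label != "unclassified" and (r.label != "constitutive" or r.secondary)
    ]
    all_phases = {p.phase_id for p in cfg.phases}
    for r in sorted(fitted, key=lambda r: r.compound):
        tree = home_tree[r.label]
        pts = ctx.emissions[
            (ctx.emissions["compound"] == r.compound)
            & (ctx.emissions["tree_id"] == tree)
        ][["day", "rate"]]
        if pts.empty:
            continue
        daily = dynamics.daily_aggregate(pts)
        if r.label in ("hipv", "stress_induced") or (r.label == "constitutive" and r.secondary):
            series[r.compound] = daily.set_index("day")["mean"]
        row = {"compound": r.compound, "tree_id": tree, "label": r.label}
        try:
            fit = dynamics.fit_extreme(daily.rename(columns={"mean": "mean"}), seed=cfg.seed)
        except ValueError as err:
            row.update(
                y0=np.nan, A=np.nan, xc=np.nan, w=np.nan,
                adj_r2=np.nan, converged=False, n_points=len(daily), message=str(err),
            )
            fit_rows.append(row)
            continue
        p = fit.params
        row.update(
            y0=p.y0 if p else np.nan,
            A=p.A if p else np.nan,
            xc=p.xc if p else np.nan,
            w=p.w if p else np.nan,
            adj_r2=fit.adj_r2,
            converged=fit.converged,
            n_points=fit.n_points,
            message=fit.message,
        )
        fit_rows.append(row)
    out["fits"] = pd.DataFrame(fit_rows)

    # correlated dynamics are grouped within each compound class
    class_of = class_of or {}
    if len(series) >= 2:
        grouping_all = dynamics.tau_group(
            series, tau_min=cfg.thresholds.tau_min, alpha=cfg.thresholds.alpha
        )
        out["tau_matrix"] = grouping_all.tau.reset_index(names="compound")
        group_rows = []
        gid = 0
        classes = sorted({class_of.get(c, "") for c in series})
        for klass in classes:
            sub = {c: s for c, s in series.items() if class_of.get(c, "") == klass}
            if len(sub) >= 2:
                grouping = dynamics.tau_group(
                    sub, tau_min=cfg.thresholds.tau_min, alpha=cfg.thresholds.alpha
                )
                partition = grouping.groups
            else:
                partition = [set(sub)]
            for g in partition:
                gid += 1
                for c in sorted(g):
                    group_rows.append(
                        {"compound": c, "compound_class": klass,
                         "group": gid, "group_size": len(g)}
                    )
        out["groups"] = pd.DataFrame(group_rows)
    else:
        out["tau_matrix"] = pd.DataFrame()
        out["groups"] = pd.DataFrame()

    # rank-based group tests on constitutive compounds, mirroring the
    # inter-tree (within phase) and intra-tree (within tree) comparisons
    test_rows = []
    for r in sorted(results, key=lambda r: r.compound):
        if r.label != "constitutive":
            continue
        for phase in sorted(all_phases):
            groups = {
                t: ctx.rates(r.compound, t, {phase}).tolist() for t in roles.all
            }
            groups = {t: g for t, g in groups.items() if len(g) >= 2}
            if len(groups) < 2:
                continue
            H, pval = dynamics.kruskal_wallis(list(groups.values()))
            sig_pairs = ""
            if pval < cfg.thresholds.alpha:
                posthoc = dynamics.dunn_posthoc(groups, alpha=cfg.thresholds.alpha)
                sig_pairs = ";".join(
                    f"{a}|{b}"
                    for a, b, s in zip(posthoc["group1"], posthoc["group2"], posthoc["significant"])
                    if s
                )
            test_rows.append(
                {
                    "compound": r.compound,
                    "comparison": f"inter_tree_phase{phase}",
                    "H": H,
                    "p": pval,
                    "significant_pairs": sig_pairs,
                }
            )
        for tree in roles.all:
            groups = {
                f"phase{ph}": ctx.rates(r.compound, tree, {ph}).tolist()
                for ph in sorted(all_phases)
            }
            groups = {k: g for k, g in groups.items() if len(g) >= 2}
            if len(groups) < 2:
                continue
            H, pval = dynamics.kruskal_wallis(list(groups.values()))
            sig_pairs = ""
            if pval < cfg.thresholds.alpha:
                posthoc = dynamics.dunn_posthoc(groups, alpha=cfg.thresholds.alpha)
                sig_pairs = ";".join(
                    f"{a}|{b}"
                    for a, b, s in zip(posthoc["group1"], posthoc["group2"], posthoc["significant"])
                    if s
                )
            test_rows.append(
                {
                    "compound": r.compound,
                    "comparison": f"intra_tree_{tree}",
                    "H": H,
                    "p": pval,
                    "significant_pairs": sig_pairs,
                }
            )
    out["tests"] = pd.DataFrame(test_rows)


def make_report(
    ctx: EmissionContext,
    results,
    compounds,
    trees,
    phases,
    annotations: pd.DataFrame,
    ratio_columns: bool = False,
) -> pd.DataFrame:
    """Build a report table over a (trees, phases) scope for given compounds.

    Per compound: experimental LRI, detection frequency over the scope,
    mean emission rate with SEM over detected samples, and the contribution
    (% of the summed mean emission rate of all compounds in the table,
    summing to 100 within rounding).  All compounds must share one rate
    unit; mixing units in one table is an error.  Report rounding follows
    the conventional table formats: DF to whole percent, contributions to
    0.01, LRI to integer.
    """
    compounds = sorted(compounds)
    if not compounds:
        return pd.DataFrame()
    units = {ctx.unit_of(c) for c in compounds}
    if len(units) > 1:
        raise ValueError(f"mixed rate units in one report table: {sorted(units)}")
    unit = units.pop()
    by_compound = {r.compound: r for r in results}
    lri_of = dict(zip(annotations["best_match"], annotations["lri_exp"]))
    means = {}
    sems = {}
    for c in compounds:
        rates = pd.concat([ctx.rates(c, t, phases) for t in trees])
        means[c] = float(rates.mean()) if len(rates) else 0.0
        sems[c] = (
            float(rates.std(ddof=1) / np.sqrt(len(rates))) if len(rates) > 1 else np.nan
        )
    total = sum(means.values())
    rows = []
    for c in compounds:
        r = by_compound.get(c)
        df = classify.detection_frequency(ctx, c, trees, phases)
        row = {
            "compound": c,
            "lri_exp": int(round(lri_of.get(c, np.nan))) if c in lri_of else "",
            "df_pct": int(round(df)),
            "n_scope": ctx.n_samples(trees, phases),
            "mean_rate": means[c],
            "sem_rate": sems[c],
            "contribution_pct": round(100.0 * means[c] / total, 2) if total > 0 else 0.0,
            "contribution_sem_pct": (
                round(100.0 * sems[c] / total, 2) if total > 0 and np.isfinite(sems[c]) else np.nan
            ),
            "unit": unit,
            "label": r.label if r else "",
            "secondary": r.secondary if r else "",
        }
        if ratio_columns and r is not None:
            for name, mark in r.ratios.items():
                row[f"ratio_{name}"] = mark.render()
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig, write: bool = True) -> dict[str, pd.DataFrame]:
    """Run every stage and (optionally) write the report bundle.

    Returns the bundle as a dict of DataFrames plus the manifest dict under
    ``"manifest"``.  Deterministic for a fixed config and seed.
    """
    th = cfg.thresholds
    roles = cfg.roles

    samples, observations = study.load_tables(cfg.design, cfg.peaks)
    obs_frame = study.observations_to_frame(observations)
    design_frame = study.samples_to_frame(samples)
    log.info("load: %d samples, %d observations", len(samples), len(observations))

    annotations = _annotate_stage(cfg, obs_frame)
    matched = annotations[annotations["best_match"] != ""]
    compound_of_feature = dict(zip(matched["feature_id"], matched["best_match"]))

    bg_ids = {s.sample_id for s in samples if s.is_background}
    trunk_obs = obs_frame[~obs_frame["sample_id"].isin(bg_ids)]
    background_obs = obs_frame[obs_frame["sample_id"].isin(bg_ids)]
    retained_features = quantify.background_filter(
        trunk_obs, background_obs, factor=th.background_factor
    )
    n_removed = len(set(trunk_obs["feature_id"])) - len(retained_features)
    log.info("background filter: removed %d ubiquitous feature(s)", n_removed)
    compound_of_feature = {
        f: c for f, c in compound_of_feature.items() if f in retained_features
    }

    curves = quantify.load_calibration(cfg.calibration)
    surrogate_map = {}
    if cfg.surrogates:
        surr = pd.read_csv(cfg.surrogates)
        surrogate_map = dict(zip(surr["compound"], surr["surrogate"]))
    emissions = quantify.build_emission_table(
        trunk_obs, samples, compound_of_feature, curves, surrogate_map
    )
    emissions = emissions.sort_values(
        ["compound", "tree_id", "day", "replicate"]
    ).reset_index(drop=True)

    ctx = EmissionContext(emissions, design_frame, phases=cfg.phases)
    results = classify_all(
        ctx,
        roles,
        retention_threshold=th.retention_df,
        constitutive_threshold=th.constitutive_df,
        min_df=th.mean_inclusion_df,
        band=th.comparability_band,
        pooled_constitutive=cfg.pooled_constitutive,
    )
    classification = classification_to_frame(results).sort_values("compound").reset_index(drop=True)
    label_counts = classification["label"].value_counts().to_dict()
    log.info("classify: %s", label_counts)

    out: dict = {
        "annotations": annotations,
        "emissions": emissions,
        "classification": classification,
    }
    class_of = dict(zip(matched["best_match"], matched["compound_class"]))
    _dynamics_stage(cfg, ctx, results, out, class_of=class_of)

    # report tables (one per label family and unit)
    constitutive = [r.compound for r in results if r.label == "constitutive"]
    out["report_constitutive"] = make_report(
        ctx, results, constitutive, roles.all, PRE_PHASES, annotations
    )
    hipvs = [r.compound for r in results if r.label == "hipv"]
    for unit in sorted({ctx.unit_of(c) for c in hipvs}):
        subset = [c for c in hipvs if ctx.unit_of(c) == unit]
        suffix = "ng" if unit == quantify.UNIT_NG else "area"
        out[f"report_induced_{suffix}"] = make_report(
            ctx, results, subset, [roles.infested], POST_PHASES, annotations,
            ratio_columns=True,
        )

    # filter-cascade bookkeeping for the manifest
    n_per_tree_phase = {
        f"{tree}_phase{ph}": int(ctx.n_samples([tree], {ph}))
        for tree in roles.all
        for ph in sorted(p.phase_id for p in cfg.phases)
    }
    retained = classify.retention_filter(ctx, th.retention_df)
    core = classify.constitutive_set(
        ctx, retained, roles, th.constitutive_df, pooled=cfg.pooled_constitutive
    )
    trees_all = set(ctx.design["tree_id"])
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_samples_total": len(samples),
        "n_trunk_samples": int(len(ctx.design)),
        "n_background_samples": int(len(bg_ids)),
        "n_samples_per_tree_phase": n_per_tree_phase,
        "n_features": int(obs_frame["feature_id"].nunique()),
        "n_features_matched": int(len(matched)),
        "n_features_retained_after_background": len(
            set(compound_of_feature)
        ),
        "n_compounds_detected": len(ctx.compounds),
        "n_retained_df10": len(retained),
        "n_constitutive_df50": len(core),
        "n_mean_eligible_df20": sum(
            1
            for c in retained
            if any(
                classify.phase_mean_rate(ctx, c, t, POST_PHASES, th.mean_inclusion_df)
                is not None
                for t in roles.all
            )
        ),
        "label_counts": {k: int(v) for k, v in sorted(label_counts.items())},
        "row_counts": {
            name: int(len(df)) for name, df in out.items() if isinstance(df, pd.DataFrame)
        },
        "thresholds": asdict(th),
    }
    out["manifest"] = manifest

    if write:
        out_dir = Path(cfg.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, obj in out.items():
            if name == "manifest":
                with open(out_dir / "manifest.json", "w") as fh:
                    json.dump(obj, fh, indent=2, sort_keys=True)
                    fh.write("\n")
            else:
                obj.to_csv(out_dir / f"{name}.csv", index=False)
    return out
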