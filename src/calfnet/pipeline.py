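"""Pipeline orchestration: config, stage runners, reports, and figures.

Stages mirror the analysis: simulate (optional, synthetic data only) ->
networks (subject selection, infancy networks, metrics) -> fit (survival
GLMM) -> agesex (class-strength permutation grid) -> cjs (resighting
probability).  Every run writes a manifest with input hashes, the seed, and
the config echo so identical inputs and seed reproduce identical output
trees byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agesex import assign_network_classes, compute_profile, profiles_table, \
    survival_comparison_grid
from .association import AssociationData, build_infancy_network, write_network
from .inference import DEFAULT_FIXED, DEFAULT_RANDOM, ModelSpec, build_design, \
    compute_vif, fit_glmm, select_model_aic
from .markrecapture import build_capture_histories, fit_cjs
from .netmetrics import metrics_table, standardize_cohort
from .simulate import PopulationConfig, generate_dataset, planted_effect_config, \
    write_dataset
from .surveys import filter_unknown_ids, read_individuals, read_surveys, \
    select_subjects

logger = logging.getLogger("calfnet")


@dataclass
class PipelineConfig:
    """Run configuration; YAML-loadable, flag-overridable."""

    out_dir: str = "calfnet_out"
    surveys_path: str | None = None      # default: <out_dir>/surveys.csv
    individuals_path: str | None = None  # default: <out_dir>/individuals.csv
    min_sightings: int = 15
    occasion_years: float = 4.0
    cjs_min_sightings: int = 15
    n_perm: int = 10000
    seed: int = 0
    count_unit: str = "days"
    model_fixed: tuple = DEFAULT_FIXED
    model_random: tuple = DEFAULT_RANDOM
    select_model: bool = False
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.model_fixed = tuple(cfg.model_fixed)
        cfg.model_random = tuple(cfg.model_random)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model_fixed"] = list(self.model_fixed)
        d["model_random"] = list(self.model_random)
        return d

    def resolve_paths(self):
        out = Path(self.out_dir)
        surveys = Path(self.surveys_path) if self.surveys_path else out / "surveys.csv"
        individuals = (Path(self.individuals_path) if self.individuals_path
                       else out / "individuals.csv")
        return out, surveys, individuals


def _write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing input file {path} ({hint})")
    return path


def run_simulate(cfg: PipelineConfig) -> dict:
    """Generate a synthetic dataset into the output directory."""
    gen_kwargs = dict(cfg.generator)
    if "survival_coefs" in gen_kwargs:
        gen_kwargs["survival_coefs"] = tuple(gen_kwargs["survival_coefs"])
    gen_kwargs.setdefault("seed", cfg.seed)
    pcfg = PopulationConfig(**gen_kwargs)
    ds = generate_dataset(pcfg)
    out, _, _ = cfg.resolve_paths()
    return write_dataset(ds, out)


def _load_inputs(cfg: PipelineConfig):
    out, surveys_path, individuals_path = cfg.resolve_paths()
    surveys = read_surveys(_require(surveys_path, "run the simulate stage or point "
                                    "surveys_path at a survey CSV"))
    individuals = read_individuals(_require(individuals_path,
                                            "individual metadata CSV"))
    surveys = filter_unknown_ids(surveys)
    return out, surveys, individuals


def run_networks(cfg: PipelineConfig) -> pd.DataFrame:
    """Select subjects, build infancy networks, write metrics and profiles."""
    out, surveys, individuals = _load_inputs(cfg)
    subjects = select_subjects(individuals, surveys, min_days=cfg.min_sightings)
    if len(subjects) < 2:
        raise ValueError(f"only {len(subjects)} analysable subjects; need >= 2")
    assoc = AssociationData(surveys)
    net_dir = out / "networks"
    net_dir.mkdir(parents=True, exist_ok=True)

    networks, profiles = {}, []
    for subject in subjects.index:
        G = build_infancy_network(subject, surveys, individuals,
                                  min_sightings=cfg.min_sightings, assoc=assoc,
                                  count_unit=cfg.count_unit)
        row = individuals.loc[subject]
        window = (row["birth_date"], row["weaning_date"])
        classes = assign_network_classes(G, surveys, individuals, window,
                                         assoc=assoc)
        for node, cls in classes.items():
            G.nodes[node]["age_class"] = cls
        networks[subject] = G
        profiles.append(compute_profile(G, subject, classes))
        write_network(G, edgelist_path=net_dir / f"{subject}.edges.csv",
                      graphml_path=net_dir / f"{subject}.graphml")

    metrics = metrics_table(networks, individuals, subjects)
    metrics = standardize_cohort(metrics)
    metrics["mother_id"] = subjects["mother_id"]
    metrics["weaning_age_years"] = subjects["weaning_age_years"]
    metrics["weaning_group"] = (
        (subjects["weaning_age_years"] / 0.5).apply(np.floor) * 0.5
    ).map(lambda v: f"{v:.1f}-{v + 0.5:.1f}y")
    metrics.to_csv(out / "metrics.csv")
    profiles_table(profiles).to_csv(out / "agesex_profiles.csv", index=False)
    logger.info("run_networks: %d subjects -> metrics.csv", len(metrics))
    return metrics


def run_fit(cfg: PipelineConfig) -> dict:
    """Fit the survival GLMM; optionally AIC-select among nested candidates."""
    out, _, _ = cfg.resolve_paths()
    metrics = pd.read_csv(_require(out / "metrics.csv", "run the networks stage"),
                          index_col=0)
    spec = ModelSpec(fixed=cfg.model_fixed, random=cfg.model_random)
    report: dict = {"seed": cfg.seed, "n_subjects": len(metrics)}

    if cfg.select_model:
        candidates = [
            spec,
            ModelSpec(fixed=tuple(t for t in cfg.model_fixed if ":" not in t),
                      random=cfg.model_random),
            ModelSpec(fixed=("sex",), random=cfg.model_random),
            ModelSpec(fixed=(), random=cfg.model_random),
        ]
        best, aic_table, fits = select_model_aic(metrics, candidates)
        report["aic_table"] = aic_table.to_dict(orient="records")
        spec = best
        fit = fits[[i for i, s in enumerate(candidates) if s is best][0]]
    else:
        fit = fit_glmm(metrics, spec)

    X, _, names = build_design(metrics, spec)
    vif = (compute_vif(pd.DataFrame(X[:, 1:], columns=names[1:]))
           if X.shape[1] > 2 else pd.Series(dtype=float))
    report.update({
        "model": spec.label(),
        "coefficients": fit.table.to_dict(orient="records"),
        "loglik": fit.loglik,
        "aic": fit.aic,
        "random_sd": fit.random_sd,
        "vif": vif.to_dict(),
        "converged": fit.converged,
        "separation": fit.separation,
    })
    _write_json(report, out / "fit_report.json")

    preds = pd.DataFrame({
        "subject_id": metrics.index,
        "sex": metrics["sex"],
        "std_eigenvector": metrics.get("std_eigenvector"),
        "survived": metrics["survived"],
        "fitted_probability": fit.fitted,
    })
    preds.to_csv(out / "predictions.csv", index=False)
    logger.info("run_fit: %s -> fit_report.json", spec.label())
    return report


def run_agesex(cfg: PipelineConfig) -> pd.DataFrame:
    """Survivor/non-survivor permutation grid over age-sex class ties."""
    out, _, _ = cfg.resolve_paths()
    profiles = pd.read_csv(_require(out / "agesex_profiles.csv",
                                    "run the networks stage"))
    metrics = pd.read_csv(_require(out / "metrics.csv", "run the networks stage"),
                          index_col=0)
    grid = survival_comparison_grid(profiles, metrics, n_perm=cfg.n_perm,
                                    seed=cfg.seed)
    _write_json({"seed": cfg.seed, "n_perm": cfg.n_perm,
                 "tests": grid.to_dict(orient="records")},
                out / "agesex_tests.json")
    logger.info("run_agesex: %d tests -> agesex_tests.json", len(grid))
    return grid


def run_cjs(cfg: PipelineConfig) -> dict:
    """Resighting-probability check on multi-year occasions."""
    out, surveys, individuals = _load_inputs(cfg)
    hist = build_capture_histories(surveys, individuals,
                                   occasion_length_years=cfg.occasion_years,
                                   min_sightings=cfg.cjs_min_sightings)
    est = fit_cjs(hist)
    report = {
        "p_detect": est.p_detect, "se_p": est.se_p,
        "phi": est.phi, "se_phi": est.se_phi,
        "loglik": est.loglik, "boundary": est.boundary,
        "n_individuals": est.n_individuals, "n_occasions": est.n_occasions,
        "occasion_length_years": cfg.occasion_years,
    }
    _write_json(report, out / "cjs_report.json")
    logger.info("run_cjs: p=%.3f +/- %.3f", est.p_detect, est.se_p)
    return report


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage (simulate first when a generator block is configured)."""
    out, surveys_path, individuals_path = cfg.resolve_paths()
    out.mkdir(parents=True, exist_ok=True)
    if cfg.generator or not surveys_path.exists():
        if cfg.generator:
            run_simulate(cfg)
    run_networks(cfg)
    fit_report = run_fit(cfg)
    grid = run_agesex(cfg)
    cjs_report = run_cjs(cfg)

    coef = {r["term"]: r["estimate"] for r in fit_report["coefficients"]}
    jm = grid[(grid["sex"] == "M") & (grid["class"] == "juvenile_M")
              & (grid["measure"] == "strength")]
    summary = {
        "n_subjects": fit_report["n_subjects"],
        "model": fit_report["model"],
        "coefficients": coef,
        "eigenvector_sex_interaction": coef.get("eigenvector:sex"),
        "juvenile_male_strength_p": (float(jm["p_value"].iloc[0])
                                     if len(jm) and pd.notna(jm["p_value"].iloc[0])
                                     else None),
        "cjs_p_detect": cjs_report["p_detect"],
    }
    _write_json(summary, out / "summary.json")

    manifest = {
        "calfnet_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "input_sha256": {
            "surveys.csv": _sha256(surveys_path),
            "individuals.csv": _sha256(individuals_path),
        },
    }
    _write_json(manifest, out / "manifest.json")
    return summary


def _weaning_groups(weaning_age_years: pd.Series) -> pd.Series:
    """Half-year weaning-age bins used as a random-intercept grouping factor."""
    lo = (weaning_age_years / 0.5).apply(np.floor) * 0.5
    return lo.map(lambda v: f"{v:.1f}-{v + 0.5:.1f}y")


def analyze_dataset(surveys: pd.DataFrame, individuals: pd.DataFrame,
                    min_sightings: int = 15, subject_min_days: int | None = None,
                    n_perm: int = 10000, seed: int = 0,
                    spec: ModelSpec | None = None) -> dict:
    """In-memory end-to-end analysis of one dataset (no file output).

    Subject selection may use a stricter sighting-day threshold
    (``subject_min_days``) than network membership (``min_sightings``).
    Returns subjects, networks, the standardized metrics table, the GLMM
    fit, and the age-sex permutation grid.
    """
    surveys = filter_unknown_ids(surveys)
    subjects = select_subjects(individuals, surveys,
                               min_days=subject_min_days or min_sightings)
    if len(subjects) < 2:
        raise ValueError(f"only {len(subjects)} analysable subjects; need >= 2")
    assoc = AssociationData(surveys)
    networks, profiles = {}, []
    for subject in subjects.index:
        G = build_infancy_network(subject, surveys, individuals,
                                  min_sightings=min_sightings, assoc=assoc)
        row = individuals.loc[subject]
        classes = assign_network_classes(G, surveys, individuals,
                                         (row["birth_date"], row["weaning_date"]),
                                         assoc=assoc)
        networks[subject] = G
        profiles.append(compute_profile(G, subject, classes))
    metrics = standardize_cohort(metrics_table(networks, individuals, subjects))
    metrics["mother_id"] = subjects["mother_id"]
    metrics["weaning_age_years"] = subjects["weaning_age_years"]
    metrics["weaning_group"] = _weaning_groups(subjects["weaning_age_years"])
    fit = fit_glmm(metrics, spec or ModelSpec())
    grid = survival_comparison_grid(profiles_table(profiles), metrics,
                                    n_perm=n_perm, seed=seed)
    return {"subjects": subjects, "networks": networks, "metrics": metrics,
            "fit": fit, "grid": grid}


def recovery_replicate(seed: int, config: PopulationConfig | None = None,
                       n_perm: int = 999, subject_min_days: int = 40) -> dict:
    """One planted-effect recovery run: simulate, analyze, summarize.

    Returns the fitted eigenvector-by-sex interaction, the juvenile-male
    strength permutation p among males, and the female-class strength
    p-values (planted-neutral controls), alongside the subject count.
    """
    pcfg = config if config is not None else planted_effect_config(seed)
    ds = generate_dataset(pcfg)
    res = analyze_dataset(ds.surveys, ds.individuals, n_perm=n_perm, seed=seed,
                          subject_min_days=subject_min_days)
    grid, fit = res["grid"], res["fit"]
    jm = grid[(grid["sex"] == "M") & (grid["class"] == "juvenile_M")
              & (grid["measure"] == "strength")]
    females = grid[(grid["sex"] == "F") & (grid["measure"] == "strength")]
    return {
        "n_subjects": len(res["subjects"]),
        "interaction": fit.coef("eigenvector:sex"),
        "interaction_se": fit.se("eigenvector:sex"),
        "jm_strength_p": (float(jm["p_value"].iloc[0])
                          if pd.notna(jm["p_value"].iloc[0]) else None),
        "jm_observed_difference": float(jm["observed_difference"].iloc[0]),
        "neutral_female_p": [float(p) for p in females["p_value"] if pd.notna(p)],
        "truth": ds.truth.planted_effects,
    }


def make_figures(cfg: PipelineConfig) -> list:
    """Static figures from the JSON/CSV outputs (never recomputed inline).

    Figure 1 analogue: fitted survival probability against standardized
    eigenvector centrality by sex.  Figure 2 analogue: mean +/- SEM age-sex
    class strength for male subjects by survival outcome, significant
    classes starred.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out, _, _ = cfg.resolve_paths()
    made = []

    preds = pd.read_csv(_require(out / "predictions.csv", "run the fit stage"))
    fig, ax = plt.subplots(figsize=(5, 4))
    for sex, marker in (("F", "o"), ("M", "s")):
        sub = preds[preds["sex"] == sex].sort_values("std_eigenvector")
        ax.plot(sub["std_eigenvector"], sub["fitted_probability"], marker,
                ms=4, label=f"sex = {sex}")
    ax.set_xlabel("standardized eigenvector centrality")
    ax.set_ylabel("fitted P(survive to age 10)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    p1 = out / "fig_survival_by_centrality.png"
    fig.savefig(p1, dpi=150)
    plt.close(fig)
    made.append(str(p1))

    with open(_require(out / "agesex_tests.json", "run the agesex stage")) as fh:
        tests = pd.DataFrame(json.load(fh)["tests"])
    male = tests[(tests["sex"] == "M") & (tests["measure"] == "strength")]
    fig, ax = plt.subplots(figsize=(6, 4))
    xs = np.arange(len(male))
    w = 0.38
    ax.bar(xs - w / 2, male["mean_survived"], w, yerr=male["sem_survived"],
           capsize=3, label="survived")
    ax.bar(xs + w / 2, male["mean_died"], w, yerr=male["sem_died"],
           capsize=3, label="died")
    for i, (_, row) in enumerate(male.iterrows()):
        if pd.notna(row["p_value"]) and row["p_value"] < 0.05:
            top = np.nanmax([row["mean_survived"] + (row["sem_survived"] or 0),
                             row["mean_died"] + (row["sem_died"] or 0)])
            ax.text(i, top * 1.05, "*", ha="center", fontsize=14)
    ax.set_xticks(xs, male["class"], rotation=30)
    ax.set_ylabel("summed HWI tie strength")
    ax.set_title("male subjects: class strength by survival outcome")
    ax.legend()
    fig.tight_layout()
    p2 = out / "fig_agesex_strength.png"
    fig.savefig(p2, dpi=150)
    plt.close(fig)
    made.append(str(p2))
    return made
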