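"""End-to-end experiments: simulate, build cohorts, train, validate.

The shipped study design mirrors a two-cohort phenotyping validation:

1. a *development* cohort with high CKD prevalence is simulated; the
   admission-time logistic classifiers (admissionHIB, historyHIB) are fit
   on a random 80 % split with Youden cutoffs calibrated on that training
   split only, and evaluated on the held-out 20 %;
2. a *validation* cohort with low prevalence is simulated independently;
   the full retrospective historyCKD forest (fit on the development
   cohort) labels it, producing a **silver standard**, while the
   generator's ground truth plays the role of the **gold standard**
   (chart review);
3. the admission-time classifiers are evaluated on the validation cohort
   against both label sets, and gold-vs-silver agreement (accuracy,
   Cohen's kappa) is reported — making any silver-standard bias visible.

Every stage appends a structured JSON log event; screening flow counts
(screened -> excluded per rule -> included) are checked to add up.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import pointbiserialr

from . import cohort as cohort_mod
from . import metrics as metrics_mod
from . import models as models_mod
from .features import PROFILE_COLUMNS, build_feature_matrices
from .synthetic import (
    RawRecordBundle,
    SimulationConfig,
    TruthLabels,
    config_from_dict,
    config_to_dict,
    generate_cohort,
    write_bundle,
)

# editable comorbidity-group map; groups are standard, exact code sets are a
# site-level convention
COMORBIDITY_PREFIXES = {
    "cardiovascular": ("I21", "I22", "I50", "I6", "I73"),
    "diabetes": ("E10", "E11", "E12", "E13", "E14"),
    "liver": ("K70", "K71", "K72", "K73", "K74", "K75", "K76", "K77"),
    "malignancy": ("C",),
}

HIB_PROFILES = ("admissionHIB", "historyHIB")


@dataclass
class CohortSection:
    profile: str = "gold"
    window: tuple[str, str] = ("2018-01-01", "2020-04-30")
    history_start: str = "2011-01-01"
    index_policy: str = "first_in_window"


@dataclass
class ModelSection:
    profiles: tuple[str, ...] = HIB_PROFILES
    split_fraction: float = 0.8
    stratify: bool = False
    seed: int = 0
    forest_trees: int = 300


@dataclass
class EvaluationSection:
    ci_method: str = "wilson"
    bootstrap_reps: int = 500
    level: float = 0.95


@dataclass
class ExperimentConfig:
    """Full experiment description; YAML-round-trippable."""

    development: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            n_patients=785, ckd_prevalence=0.48, seed=101
        )
    )
    validation: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            n_patients=1075, ckd_prevalence=0.12, seed=202
        )
    )
    cohort: CohortSection = field(default_factory=CohortSection)
    model: ModelSection = field(default_factory=ModelSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)
    output_dir: str = "ckdphen_run"

    def to_dict(self) -> dict:
        return {
            "development": config_to_dict(self.development),
            "validation": config_to_dict(self.validation),
            "cohort": {
                "profile": self.cohort.profile,
                "window": list(self.cohort.window),
                "history_start": self.cohort.history_start,
                "index_policy": self.cohort.index_policy,
            },
            "model": {
                "profiles": list(self.model.profiles),
                "split_fraction": self.model.split_fraction,
                "stratify": self.model.stratify,
                "seed": self.model.seed,
                "forest_trees": self.model.forest_trees,
            },
            "evaluation": dataclasses.asdict(self.evaluation),
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = {}
        if "development" in d:
            kwargs["development"] = config_from_dict(d["development"])
        if "validation" in d:
            kwargs["validation"] = config_from_dict(d["validation"])
        if "cohort" in d:
            c = dict(d["cohort"])
            if "window" in c:
                c["window"] = tuple(c["window"])
            kwargs["cohort"] = CohortSection(**c)
        if "model" in d:
            m = dict(d["model"])
            if "profiles" in m:
                m["profiles"] = tuple(m["profiles"])
            kwargs["model"] = ModelSection(**m)
        if "evaluation" in d:
            kwargs["evaluation"] = EvaluationSection(**d["evaluation"])
        if "output_dir" in d:
            kwargs["output_dir"] = d["output_dir"]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class BuiltCohort:
    """A simulated cohort flattened, linked, filtered and featurized."""

    data: cohort_mod.FlattenedData
    linked_stays: pd.DataFrame
    included: list[str]
    exclusion_log: pd.DataFrame
    no_stay_in_window: list[str]
    features: dict[str, pd.DataFrame]  # profile -> matrix
    truth: pd.Series  # ckd_true over included patients
    flow: dict  # screening flow counts


def build_cohort(
    bundle: RawRecordBundle,
    truth: TruthLabels,
    cohort_cfg: CohortSection,
    profiles=("admissionHIB", "historyHIB", "historyCKD"),
) -> BuiltCohort:
    """Flatten -> link -> criteria -> feature matrices for each profile."""
    data = cohort_mod.flatten_bundle(bundle)
    linked, no_index = cohort_mod.link_stays(
        data.stays, cohort_cfg.window, cohort_cfg.history_start,
        cohort_cfg.index_policy,
    )
    included, excl_log = cohort_mod.apply_inclusion_criteria(
        data, linked, cohort_cfg.profile
    )
    features = build_feature_matrices(data, linked, included, profiles)
    truth_s = (
        truth.labels.set_index("patient_id")["ckd_true"].loc[included].astype(bool)
    )
    flow = {
        "screened": int(len(data.patients)),
        "no_stay_in_window": int(len(no_index)),
        "excluded_by_rule": {
            rule: int((excl_log["rule"] == rule).sum())
            for rule in cohort_mod.EXCLUSION_ORDER
        },
        "included": int(len(included)),
    }
    total = (
        flow["no_stay_in_window"]
        + sum(flow["excluded_by_rule"].values())
        + flow["included"]
    )
    if total != flow["screened"]:
        raise RuntimeError("exclusion accounting does not sum to screened count")
    return BuiltCohort(
        data=data,
        linked_stays=linked,
        included=included,
        exclusion_log=excl_log,
        no_stay_in_window=no_index,
        features=features,
        truth=truth_s,
        flow=flow,
    )


def run_training_experiment(
    config: ExperimentConfig,
) -> tuple[dict, dict, dict, "models_mod.ForestLabeler", BuiltCohort]:
    """Fit the HIB classifiers and the historyCKD forest on the development cohort.

    Returns (results per profile, test MetricSets, test CurveSets, forest,
    built development cohort).  Cutoffs are Youden-calibrated on the
    training split only; metrics come from the held-out split.
    """
    bundle, truth = generate_cohort(config.development)
    built = build_cohort(bundle, truth, config.cohort)
    y = built.truth
    train_ids, test_ids = models_mod.split_train_test(
        y.index.to_numpy(),
        fraction=config.model.split_fraction,
        seed=config.model.seed,
        labels=y.to_numpy(),
        stratify=config.model.stratify,
    )
    results: dict[str, models_mod.CkdLogitResults] = {}
    test_metrics: dict[str, metrics_mod.MetricSet] = {}
    test_curves: dict[str, metrics_mod.CurveSet] = {}
    for profile in config.model.profiles:
        X = built.features[profile]
        model = models_mod.CkdLogit(X.loc[train_ids], y.loc[train_ids], profile)
        res = model.fit(calibrate_cutoff=True)
        results[profile] = res
        scores = res.predict(X.loc[test_ids])
        pred = scores >= res.cutoff
        cm = metrics_mod.ConfusionMatrix.from_labels(pred, y.loc[test_ids].to_numpy())
        test_metrics[profile] = metrics_mod.classification_metrics(
            cm, config.evaluation.level, config.evaluation.ci_method
        )
        roc = metrics_mod.roc_and_auc(scores, y.loc[test_ids].to_numpy())
        pr = metrics_mod.pr_and_auc(
            scores,
            y.loc[test_ids].to_numpy(),
            bootstrap=config.evaluation.bootstrap_reps,
            seed=config.model.seed,
        )
        test_curves[profile] = metrics_mod.CurveSet(
            roc_points=roc.roc_points,
            pr_points=pr.pr_points,
            auroc=roc.auroc,
            auroc_ci=roc.auroc_ci,
            auprc=pr.auprc,
            auprc_ci=pr.auprc_ci,
            methods={**roc.methods, **pr.methods},
        )
    forest = models_mod.fit_reference_forest(
        built.features["historyCKD"].loc[train_ids],
        y.loc[train_ids],
        seed=config.model.seed,
        n_estimators=config.model.forest_trees,
    )
    return results, test_metrics, test_curves, forest, built


def generate_silver_labels(
    forest: "models_mod.ForestLabeler", features: pd.DataFrame
) -> pd.DataFrame:
    """Apply the historyCKD labeler to a cohort's feature matrix."""
    if features.empty:
        return pd.DataFrame(columns=["silver_prob", "silver_label"])
    probs = forest.predict(features)
    return pd.DataFrame(
        {"silver_prob": probs, "silver_label": probs >= forest.cutoff},
        index=features.index,
    )


def compare_gold_silver(
    gold: pd.Series, silver: pd.Series
) -> metrics_mod.AgreementReport:
    """Agreement between gold (chart-review stand-in) and silver labels."""
    return metrics_mod.agreement_report(gold, silver)


def characterize_cohort(
    patients: pd.DataFrame,
    linked_stays: pd.DataFrame,
    included: list[str],
    labels: pd.Series,
    conditions: pd.DataFrame,
    admission_egfr: pd.Series,
) -> dict:
    """Cohort characterization table: demographics, admission eGFR, comorbidity.

    Returns a nested dict with one block per group (cohort / CKD / noCKD):
    n, age mean & SD, male count & %, admission-eGFR median & quartiles,
    and comorbidity-group counts & %, plus the age-CKD point-biserial
    correlation.
    """
    pat = patients.set_index("patient_id").loc[included]
    index_stays = (
        linked_stays[linked_stays["is_index"]].set_index("patient_id").loc[included]
    )
    age = pd.Series(
        {
            pid: cohort_mod.age_at(pat.loc[pid, "birth_date"],
                                   index_stays.loc[pid, "admission"])
            for pid in included
        }
    )
    male = pat["sex"].astype(str).str.lower().str.startswith("m")
    codes_by_patient = conditions.groupby("patient_id")["code"].apply(list).to_dict()

    def has_group(pid: str, prefixes: tuple[str, ...]) -> bool:
        return any(
            str(c).startswith(prefixes) for c in codes_by_patient.get(pid, [])
        )

    def block(ids: pd.Index) -> dict:
        n = len(ids)
        if n == 0:
            return {"n": 0}
        a = age.loc[ids]
        g = admission_egfr.loc[ids]
        out = {
            "n": n,
            "age_mean": float(a.mean()),
            "age_sd": float(a.std(ddof=1)) if n > 1 else 0.0,
            "male_n": int(male.loc[ids].sum()),
            "male_pct": float(100.0 * male.loc[ids].mean()),
            "egfr_admission_median": float(g.median()),
            "egfr_admission_q1": float(g.quantile(0.25)),
            "egfr_admission_q3": float(g.quantile(0.75)),
        }
        for group, prefixes in COMORBIDITY_PREFIXES.items():
            cnt = sum(has_group(pid, prefixes) for pid in ids)
            out[f"{group}_n"] = int(cnt)
            out[f"{group}_pct"] = float(100.0 * cnt / n)
        return out

    lab = labels.loc[included].astype(bool)
    ids_all = pd.Index(included)
    result = {
        "cohort": block(ids_all),
        "CKD": block(ids_all[lab.to_numpy()]),
        "noCKD": block(ids_all[~lab.to_numpy()]),
    }
    if lab.nunique() == 2:
        r, _ = pointbiserialr(lab.to_numpy().astype(float), age.to_numpy())
        result["age_ckd_pointbiserial_r"] = float(r)
    else:
        result["age_ckd_pointbiserial_r"] = float("nan")
    if result["CKD"]["n"] + result["noCKD"]["n"] != result["cohort"]["n"]:
        raise RuntimeError("group counts do not sum to cohort size")
    return result


def _metricset_to_dict(ms: metrics_mod.MetricSet) -> dict:
    return {
        m: {
            "point": None if m in ms.undefined else round(ms.points[m], 6),
            "ci_low": None if m in ms.undefined else round(ms.ci_low[m], 6),
            "ci_high": None if m in ms.undefined else round(ms.ci_high[m], 6),
        }
        for m in metrics_mod.METRIC_NAMES
    }


def informative_history_config(seed: int, n_patients: int = 600) -> SimulationConfig:
    """Development-style cohort where pre-admission history is informative.

    High measurement noise (CV 0.35) blurs the single admission eGFR while
    the mean over previous-stay measurements averages it out, so a
    classifier with access to history should beat the admission-only one.
    Prevalence matches a development cohort (48 %).
    """
    return SimulationConfig(
        n_patients=n_patients,
        ckd_prevalence=0.48,
        seed=seed,
        creatinine_noise_cv=0.35,
        target_egfr_ckd_range=(20.0, 55.0),
        target_egfr_nonckd_range=(62.0, 105.0),
        stays_per_patient_rate=2.5,
    )


def _test_f1(pred: np.ndarray, truth: np.ndarray) -> float:
    cm = metrics_mod.ConfusionMatrix.from_labels(pred, truth)
    return metrics_mod.classification_metrics(cm).points["f1"]


def history_benefit_trial(seed: int, n_patients: int = 600) -> dict[str, float]:
    """Held-out F1 of admissionHIB vs historyHIB on one informative-history cohort."""
    bundle, truth = generate_cohort(informative_history_config(seed, n_patients))
    built = build_cohort(bundle, truth, CohortSection(),
                         profiles=("admissionHIB", "historyHIB"))
    y = built.truth
    train_ids, test_ids = models_mod.split_train_test(
        y.index.to_numpy(), 0.8, seed, labels=y.to_numpy()
    )
    out = {}
    for profile in ("admissionHIB", "historyHIB"):
        X = built.features[profile]
        res = models_mod.CkdLogit(X.loc[train_ids], y.loc[train_ids], profile).fit()
        pred = res.predict(X.loc[test_ids]) >= res.cutoff
        out[profile] = _test_f1(pred, y.loc[test_ids].to_numpy())
    return out


def silver_fidelity_trial(
    seed: int,
    n_development: int = 600,
    n_validation: int = 600,
    forest_trees: int = 200,
) -> dict:
    """One seed of the silver-standard fidelity experiment.

    Fits the historyCKD forest and the HIB classifiers on a development
    cohort, labels an independent validation cohort with the forest
    (silver standard), and returns the forest's held-out F1, the
    gold-vs-silver kappa, and each HIB classifier's F1 against both label
    sets on the validation cohort.
    """
    dev_cfg = SimulationConfig(
        n_patients=n_development, ckd_prevalence=0.48, seed=seed * 2 + 1
    )
    val_cfg = SimulationConfig(
        n_patients=n_validation, ckd_prevalence=0.12, seed=seed * 2 + 2
    )
    cohort_cfg = CohortSection()
    dev_bundle, dev_truth = generate_cohort(dev_cfg)
    dev = build_cohort(dev_bundle, dev_truth, cohort_cfg)
    y = dev.truth
    train_ids, test_ids = models_mod.split_train_test(
        y.index.to_numpy(), 0.8, seed, labels=y.to_numpy()
    )
    forest = models_mod.fit_reference_forest(
        dev.features["historyCKD"].loc[train_ids],
        y.loc[train_ids],
        seed=seed,
        n_estimators=forest_trees,
    )
    forest_test_f1 = _test_f1(
        forest.classify(dev.features["historyCKD"].loc[test_ids]),
        y.loc[test_ids].to_numpy(),
    )
    hib = {
        p: models_mod.CkdLogit(
            dev.features[p].loc[train_ids], y.loc[train_ids], p
        ).fit()
        for p in HIB_PROFILES
    }

    val_bundle, val_truth = generate_cohort(val_cfg)
    val = build_cohort(val_bundle, val_truth, cohort_cfg)
    gold = val.truth
    silver = generate_silver_labels(forest, val.features["historyCKD"])["silver_label"]
    agreement = compare_gold_silver(gold, silver)

    out = {"forest_test_f1": forest_test_f1, "kappa": agreement.kappa,
           "n_overlap": agreement.n_overlap}
    for p, res in hib.items():
        pred = res.predict(val.features[p]) >= res.cutoff
        out[f"f1_gold_{p}"] = _test_f1(pred, gold.to_numpy())
        out[f"f1_silver_{p}"] = _test_f1(pred, silver.loc[val.features[p].index].to_numpy())
    return out


def run_full_study(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run the complete two-cohort study and write machine-readable reports.

    Returns the report dict; when ``out_dir`` is given, writes
    ``report.json``, ``models/*.json``, the config snapshot and a
    structured stage log there.
    """
    events: list[dict] = []

    def log(stage: str, **info):
        events.append({"stage": stage, **info})

    log("config", hash=config.config_hash())
    results, dev_metrics, dev_curves, forest, dev_built = run_training_experiment(
        config
    )
    log("train", flow=dev_built.flow,
        profiles={p: r.cutoff for p, r in results.items()})

    val_bundle, val_truth = generate_cohort(config.validation)
    val_built = build_cohort(val_bundle, val_truth, config.cohort)
    log("validation_cohort", flow=val_built.flow)

    gold = val_built.truth
    silver_frame = generate_silver_labels(forest, val_built.features["historyCKD"])
    silver = silver_frame["silver_label"]
    agreement = compare_gold_silver(gold, silver)
    log("silver_standard", n=int(len(silver)),
        prevalence=float(silver.mean()), kappa=agreement.kappa)

    validation_metrics: dict[str, dict] = {}
    for profile, res in results.items():
        X = val_built.features[profile]
        scores = res.predict(X)
        pred = scores >= res.cutoff
        block = {}
        for ref_name, ref in (("gold", gold), ("silver", silver)):
            cm = metrics_mod.ConfusionMatrix.from_labels(
                pred, ref.loc[X.index].to_numpy()
            )
            ms = metrics_mod.classification_metrics(
                cm, config.evaluation.level, config.evaluation.ci_method
            )
            roc = metrics_mod.roc_and_auc(scores, ref.loc[X.index].to_numpy())
            pr = metrics_mod.pr_and_auc(
                scores,
                ref.loc[X.index].to_numpy(),
                bootstrap=config.evaluation.bootstrap_reps,
                seed=config.model.seed,
            )
            block[ref_name] = {
                "metrics": _metricset_to_dict(ms),
                "auroc": round(roc.auroc, 6),
                "auroc_ci": [round(x, 6) for x in roc.auroc_ci],
                "auprc": round(pr.auprc, 6),
                "auprc_ci": (
                    [round(x, 6) for x in pr.auprc_ci] if pr.auprc_ci else None
                ),
            }
        validation_metrics[profile] = block

    characteristics = characterize_cohort(
        val_built.data.patients,
        val_built.linked_stays,
        val_built.included,
        gold,
        val_built.data.conditions,
        val_built.features["admissionHIB"]["egfr_admission"],
    )

    report = {
        "config_hash": config.config_hash(),
        "development": {
            "flow": dev_built.flow,
            "prevalence": round(float(dev_built.truth.mean()), 6),
            "test_metrics": {
                p: _metricset_to_dict(m) for p, m in dev_metrics.items()
            },
            "test_auroc": {p: round(c.auroc, 6) for p, c in dev_curves.items()},
            "test_auprc": {p: round(c.auprc, 6) for p, c in dev_curves.items()},
            "cutoffs": {p: round(r.cutoff, 6) for p, r in results.items()},
        },
        "validation": {
            "flow": val_built.flow,
            "gold_prevalence": round(float(gold.mean()), 6),
            "silver_prevalence": round(float(silver.mean()), 6),
            "metrics": validation_metrics,
            "gold_silver_agreement": {
                "n_overlap": agreement.n_overlap,
                "accuracy": round(agreement.accuracy, 6),
                "kappa": round(agreement.kappa, 6),
            },
            "characteristics": characteristics,
        },
        "log": events,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        config.to_yaml(out / "config_snapshot.yaml")
        (out / "log.json").write_text(json.dumps(events, indent=2, sort_keys=True))
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for profile, res in results.items():
            res.to_json(models_dir / f"{profile}.json")
        curves_dir = out / "curves"
        curves_dir.mkdir(exist_ok=True)
        for profile, cs in dev_curves.items():
            cs.roc_points.to_csv(curves_dir / f"{profile}_roc.csv", index=False)
            cs.pr_points.to_csv(curves_dir / f"{profile}_pr.csv", index=False)
    return report
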