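"""CKD classifiers: rule-based flags and trainable models with Youden cutoffs.

Three rule-based classifiers mirror what large registries typically use —
an index-stay eGFR threshold, ICD-10 billing codes, and a binary
discharge-summary CKD mention.  The trainable classifiers are a logistic
model per predictor profile (the admission-time biobanking classifiers)
and a random-forest contract for the full retrospective profile, which
acts as the silver-standard labeler.

The logistic model follows the Model/Results idiom: :class:`CkdLogit` is
built from a feature matrix and labels, ``fit()`` returns a
:class:`CkdLogitResults` carrying coefficients, standard errors, a
convergence/separation diagnosis, the calibrated decision cutoff and a
``summary()`` table; prediction and serialization hang off the results
object.

Decision conventions: a score exactly at the cutoff classifies positive
(``>=``); the Youden cutoff is the lowest threshold maximizing
sensitivity + specificity - 1 over midpoints of consecutive distinct
scores (plus the extremes).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

DEFAULT_ICD_PREFIXES = ("N18.3", "N18.4", "N18.5", "N18.9")

# decision cutoffs published for the original admission-time classifiers,
# derived from their (restricted) training cohort; shipped for workflow
# parity only — every executable model here is refit and recalibrated
PUBLISHED_CUTOFFS = {"historyHIB": 0.586, "admissionHIB": 0.478}


@dataclass
class RuleConfig:
    """Configuration of the rule-based classifiers."""

    egfr_threshold: float = 60.0
    egfr_aggregation: str = "max_lt"  # max_lt | any_lt | all_lt
    icd_prefixes: tuple[str, ...] = DEFAULT_ICD_PREFIXES
    summary_missing_as_negative: bool = True

    def __post_init__(self) -> None:
        if self.egfr_threshold <= 0:
            raise ValueError("egfr_threshold must be positive")
        if not self.icd_prefixes:
            raise ValueError("icd code set must be non-empty")
        if self.egfr_aggregation not in ("max_lt", "any_lt", "all_lt"):
            raise ValueError(f"unknown aggregation {self.egfr_aggregation!r}")


def rule_egfr_index(egfr_values, config: RuleConfig | None = None) -> bool:
    """Index-stay eGFR rule; default: every value (i.e. the max) below 60."""
    config = config or RuleConfig()
    g = np.asarray(egfr_values, dtype=float)
    if g.size == 0:
        raise ValueError("need at least one eGFR value")
    thr = config.egfr_threshold
    if config.egfr_aggregation == "any_lt":
        return bool((g < thr).any())
    # max_lt and all_lt coincide: max(series) < thr  <=>  all below thr
    return bool(g.max() < thr)


def rule_icd10(codes, config: RuleConfig | None = None) -> bool:
    """True iff any ICD-10 code starts with a configured CKD prefix."""
    config = config or RuleConfig()
    return any(
        str(c).startswith(tuple(config.icd_prefixes)) for c in codes if pd.notna(c)
    )


def rule_discharge_summary(flag, config: RuleConfig | None = None,
                           log: list | None = None) -> bool:
    """Pass the binary discharge-summary CKD mention through.

    A missing flag is treated as negative and logged — a patient without a
    discharge summary cannot be rule-positive.
    """
    if flag is None or (isinstance(flag, float) and np.isnan(flag)):
        if log is not None:
            log.append("missing discharge-summary flag treated as negative")
        return False
    return bool(flag)


def split_train_test(
    index, fraction: float = 0.8, seed: int = 0, labels=None, stratify: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint, exhaustive train/test split of an index.

    Train size is ``floor(fraction * n)``; the remainder is the test set.
    Optionally stratified by binary label.  Reproducible under ``seed``.
    """
    idx = np.asarray(index)
    n = len(idx)
    if n < 5:
        raise ValueError("need at least 5 records to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    if stratify:
        if labels is None:
            raise ValueError("stratified split requires labels")
        lab = np.asarray(labels).astype(bool)
        train_mask = np.zeros(n, dtype=bool)
        for cls in (False, True):
            cls_pos = np.flatnonzero(lab == cls)
            k = int(np.floor(fraction * cls_pos.size))
            train_mask[rng.permutation(cls_pos)[:k]] = True
    else:
        k = int(np.floor(fraction * n))
        train_mask = np.zeros(n, dtype=bool)
        train_mask[rng.permutation(n)[:k]] = True
    return idx[train_mask], idx[~train_mask]


def youden_j(scores, labels, threshold: float) -> float:
    """Sensitivity + specificity - 1 at a threshold (positive iff score >= t)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pred = s >= threshold
    sens = (pred & y).sum() / y.sum()
    spec = (~pred & ~y).sum() / (~y).sum()
    return float(sens + spec - 1.0)


def select_cutoff_youden(scores, labels) -> float:
    """Cutoff maximizing the Youden index over observed-score midpoints.

    Candidates are the midpoints between consecutive distinct scores plus
    the two extremes; ties resolve to the lowest threshold.  With
    uninformative (all-equal) scores the common score is returned with a
    warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to calibrate a cutoff")
    uniq = np.unique(s)
    if uniq.size == 1:
        warnings.warn("all scores identical; Youden index is 0 everywhere")
        return float(uniq[0])
    gap = uniq[-1] - uniq[0]
    candidates = np.concatenate(
        ([uniq[0] - 0.5 * gap], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 0.5 * gap])
    )
    js = np.array([youden_j(s, y, t) for t in candidates])
    return float(candidates[int(np.argmax(js))])  # argmax -> lowest on ties


class CkdLogit:
    """Logistic CKD classifier for one predictor profile.

    Parameters
    ----------
    features : DataFrame
        Patients x predictors, columns in the profile's documented order.
    labels : array-like of bool
        CKD status per patient (aligned with ``features``).
    profile : str
        Profile identity stamped into results and serialized models.
    """

    def __init__(self, features: pd.DataFrame, labels, profile: str = "custom"):
        self.features = features.astype(float)
        self.labels = np.asarray(labels).astype(bool)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must align")
        self.profile = profile

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_col: str = "ckd_true",
                       profile: str = "custom") -> "CkdLogit":
        X = frame.drop(columns=[label_col])
        return cls(X, frame[label_col].to_numpy(), profile)

    def fit(self, calibrate_cutoff: bool = True, seed: int = 0) -> "CkdLogitResults":
        """Unpenalized maximum-likelihood fit with Youden cutoff calibration.

        Quasi-separated data fall back to an L2-regularized fit and are
        flagged on the results object; zero-variance columns are dropped
        with a warning rather than producing an unidentifiable
        coefficient.
        """
        y = self.labels
        if y.all() or not y.any():
            raise ValueError("both classes required to fit a classifier")
        X = self.features.copy()
        dropped = [c for c in X.columns if X[c].nunique() <= 1]
        if dropped:
            warnings.warn(f"dropping zero-variance feature(s): {dropped}")
            X = X.drop(columns=dropped)
        Xc = sm.add_constant(X, has_constant="add")
        separation = False
        converged = False
        params = bse = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y.astype(float), Xc).fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", False))
                params = res.params
                bse = res.bse
                if not converged or not np.all(np.isfinite(res.bse)) or \
                        np.max(np.abs(res.params)) > 1e3:
                    separation = True
            except Exception:
                separation = True
        if separation:
            # ridge fallback keeps coefficients finite under separation;
            # standard errors are no longer valid and are reported as NaN
            lr = LogisticRegression(C=1.0, max_iter=1000)
            lr.fit(X.to_numpy(), y)
            params = pd.Series(
                np.concatenate(([lr.intercept_[0]], lr.coef_[0])), index=Xc.columns
            )
            bse = pd.Series(np.nan, index=Xc.columns)
            converged = True
            warnings.warn(
                "quasi-separation detected; fell back to ridge-regularized fit"
            )
        result = CkdLogitResults(
            profile=self.profile,
            feature_names=list(X.columns),
            params=params,
            bse=bse,
            converged=converged,
            separation=separation,
            n_obs=len(y),
            dropped_features=dropped,
        )
        if calibrate_cutoff:
            scores = result.predict(X)
            result.cutoff = select_cutoff_youden(scores, y)
        return result


@dataclass
class CkdLogitResults:
    """Fitted logistic CKD classifier: estimates, uncertainty, cutoff."""

    profile: str
    feature_names: list[str]
    params: pd.Series  # includes "const"
    bse: pd.Series
    converged: bool
    separation: bool
    n_obs: int
    cutoff: float = 0.5
    dropped_features: list[str] = field(default_factory=list)

    def _design(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise KeyError(f"missing feature(s): {missing}")
        return features[self.feature_names].to_numpy(dtype=float)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Predicted CKD probability (inverse-logit of the linear index)."""
        X = self._design(features)
        beta = self.params[self.feature_names].to_numpy()
        return expit(self.params["const"] + X @ beta)

    def classify(self, features: pd.DataFrame) -> np.ndarray:
        """Binary call: positive iff score >= cutoff (ties positive)."""
        return self.predict(features) >= self.cutoff

    def summary(self) -> str:
        lines = [
            f"CkdLogit results — profile {self.profile}, n = {self.n_obs}",
            f"converged: {self.converged}   separation fallback: {self.separation}",
            f"decision cutoff (Youden, training data): {self.cutoff:.3f}",
            f"{'term':<28}{'coef':>12}{'std err':>12}",
        ]
        for name in ["const", *self.feature_names]:
            se = self.bse[name]
            se_s = f"{se:12.4f}" if np.isfinite(se) else f"{'--':>12}"
            lines.append(f"{name:<28}{self.params[name]:12.4f}{se_s}")
        if self.dropped_features:
            lines.append(f"dropped zero-variance: {self.dropped_features}")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "profile": self.profile,
            "feature_names": self.feature_names,
            "intercept": float(self.params["const"]),
            "coefficients": [float(self.params[c]) for c in self.feature_names],
            "bse": {
                k: (float(v) if np.isfinite(v) else None) for k, v in self.bse.items()
            },
            "cutoff": float(self.cutoff),
            "converged": self.converged,
            "separation": self.separation,
            "n_obs": self.n_obs,
            "conventions": {"positive_if": "score >= cutoff"},
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CkdLogitResults":
        p = Path(source)
        doc = json.loads(p.read_text() if p.exists() else str(source))
        names = doc["feature_names"]
        params = pd.Series(
            [doc["intercept"], *doc["coefficients"]], index=["const", *names]
        )
        bse = pd.Series(
            {k: (np.nan if v is None else v) for k, v in doc["bse"].items()}
        )
        return cls(
            profile=doc["profile"],
            feature_names=names,
            params=params,
            bse=bse,
            converged=doc["converged"],
            separation=doc["separation"],
            n_obs=doc["n_obs"],
            cutoff=doc["cutoff"],
        )


@dataclass
class ForestLabeler:
    """Random-forest contract for the historyCKD silver-standard labeler.

    Deterministic given its seed; exposes per-patient probabilities and a
    Youden-calibrated binary call like the logistic results object.
    """

    profile: str
    feature_names: list[str]
    estimator: RandomForestClassifier
    cutoff: float = 0.5
    seed: int = 0

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_names].to_numpy(dtype=float)
        return self.estimator.predict_proba(X)[:, 1]

    def classify(self, features: pd.DataFrame) -> np.ndarray:
        return self.predict(features) >= self.cutoff


def fit_reference_forest(
    features: pd.DataFrame,
    labels,
    seed: int = 0,
    n_estimators: int = 300,
    calibrate_cutoff: bool = True,
) -> ForestLabeler:
    """Fit the historyCKD random-forest labeler."""
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes required to fit a classifier")
    est = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    est.fit(features.to_numpy(dtype=float), y)
    labeler = ForestLabeler(
        profile="historyCKD",
        feature_names=list(features.columns),
        estimator=est,
        seed=seed,
    )
    if calibrate_cutoff:
        scores = labeler.predict(features)
        if np.unique(scores).size > 1:
            labeler.cutoff = select_cutoff_youden(scores, y)
    return labeler
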