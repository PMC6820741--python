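"""Longitudinal clinical features and the neutrophil/lymphocyte subgroup classifier.

The classifier's input features are per-patient Pearson correlations of
cell percentages with disease activity across visits: dNeu (neutrophil %
vs SLEDAI), dLym (lymphocyte % vs SLEDAI) and dNLR (the
neutrophil-to-lymphocyte ratio vs SLEDAI).  A logistic regression on one
or more of those features predicts whether a patient's disease activity
is neutrophil- or lymphocyte-driven.

``reference_model`` exposes the published model f(x) = 0.3438 + 1.9848*x
on dNeu, calling a patient neutrophil-driven when the linear predictor
exceeds 0.18 (the boundary itself is lymphocyte-driven).  ``fit_classifier``
refits from data with repeated k-fold cross-validation for feature-set
selection; newly fitted models pick their decision cutoff on training data
by Youden's J.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr, rankdata

from .core_io import ClinicalTable
from .errors import ValidationError

NEUTROPHIL = "neutrophil_driven"
LYMPHOCYTE = "lymphocyte_driven"

FEATURE_NAMES = ("dNeu", "dLym", "dNLR")


@dataclass
class PatientFeatures:
    patient_id: str
    n_visits: int
    dNeu: float
    dLym: float
    dNLR: float
    label: str | None = None

    def get(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class ClassifierModel:
    intercept: float
    slopes: dict[str, float]
    decision_cutoff: float
    feature_set: tuple[str, ...]
    cv_summary: dict = field(default_factory=dict)

    def linear_predictor(self, f: PatientFeatures | dict) -> float:
        total = self.intercept
        for name, slope in self.slopes.items():
            value = f.get(name) if hasattr(f, "get") else getattr(f, name)
            if value is None or not np.isfinite(value):
                raise ValidationError(f"feature {name} undefined for this patient")
            total += slope * value
        return total

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "slopes": self.slopes,
            "decision_cutoff": self.decision_cutoff,
            "feature_set": list(self.feature_set),
            "cv_summary": self.cv_summary,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            intercept=payload["intercept"],
            slopes=dict(payload["slopes"]),
            decision_cutoff=payload["decision_cutoff"],
            feature_set=tuple(payload["feature_set"]),
            cv_summary=payload.get("cv_summary", {}),
        )


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(pearsonr(x, y)[0])


def longitudinal_features(
    clinical: ClinicalTable, min_visits: int = 3
) -> tuple[list[PatientFeatures], list[tuple[str, str]]]:
    """Per-patient correlation features over their visit series.

    Patients with fewer than ``min_visits`` visits, or with a zero-variance
    SLEDAI or cell-percentage series (correlation undefined), are excluded
    and returned with the reason.
    """
    features: list[PatientFeatures] = []
    excluded: list[tuple[str, str]] = []
    for patient, grp in clinical.data.groupby("patient_id"):
        patient = str(patient)
        if len(grp) < min_visits:
            excluded.append((patient, f"only {len(grp)} visits (< {min_visits})"))
            continue
        sledai = grp["sledai"].to_numpy(dtype=float)
        neut = grp["neut_pct"].to_numpy(dtype=float)
        lymph = grp["lymph_pct"].to_numpy(dtype=float)
        if np.std(sledai) == 0:
            excluded.append((patient, "constant SLEDAI series"))
            continue
        d_neu = _safe_corr(neut, sledai)
        d_lym = _safe_corr(lymph, sledai)
        with np.errstate(divide="ignore", invalid="ignore"):
            nlr = np.where(lymph > 0, neut / lymph, np.nan)
        valid = np.isfinite(nlr)
        d_nlr = _safe_corr(nlr[valid], sledai[valid]) if valid.sum() >= min_visits else np.nan
        if not np.isfinite(d_neu) and not np.isfinite(d_lym):
            excluded.append((patient, "zero-variance cell series"))
            continue
        features.append(
            PatientFeatures(
                patient_id=patient,
                n_visits=len(grp),
                dNeu=d_neu,
                dLym=d_lym,
                dNLR=d_nlr,
            )
        )
    return features, excluded


def _features_matrix(
    features: list[PatientFeatures], names: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    rows, kept = [], []
    for f in features:
        vals = [f.get(n) for n in names]
        if all(v is not None and np.isfinite(v) for v in vals):
            rows.append(vals)
            kept.append(f.patient_id)
    return np.asarray(rows, dtype=float), kept


def _fit_logit(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Maximum-likelihood logistic fit (IRLS via statsmodels Logit)."""
    design = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception as exc:
            raise ValidationError(f"logistic fit failed to converge: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValidationError("logistic fit produced non-finite coefficients")
    return params


def _youden_cutoff(predictor: np.ndarray, y: np.ndarray) -> float:
    """Cutoff on the linear predictor maximizing sensitivity + specificity - 1."""
    order = np.argsort(predictor)
    thresholds = np.concatenate(
        ([predictor.min() - 1.0], (predictor[order][1:] + predictor[order][:-1]) / 2.0,
         [predictor.max() + 1.0])
    )
    pos, neg = (y == 1).sum(), (y == 0).sum()
    best_j, best_t = -np.inf, 0.0
    for t in thresholds:
        pred = predictor > t
        tpr = (pred & (y == 1)).sum() / max(pos, 1)
        fpr = (pred & (y == 0)).sum() / max(neg, 1)
        j = tpr - fpr
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def fit_classifier(
    features: list[PatientFeatures],
    labels: dict[str, str] | pd.Series,
    feature_sets: list[tuple[str, ...]] | None = None,
    k: int = 10,
    n_iter: int = 1000,
    seed: int | None = None,
) -> tuple[dict[tuple[str, ...], ClassifierModel], tuple[str, ...]]:
    """Repeated k-fold CV over candidate feature sets; refit the best on all data.

    Accuracy for a feature set is the mean held-out accuracy over
    ``n_iter`` random re-partitions into ``k`` folds, with the decision
    cutoff chosen on each training split by Youden's J.  Returns one fitted
    model per feature set and the name of the best (highest mean CV
    accuracy) set.
    """
    if feature_sets is None:
        feature_sets = [("dNeu",), ("dLym",), ("dNLR",), ("dNeu", "dLym"),
                        ("dNeu", "dLym", "dNLR")]
    if k < 2:
        raise ValidationError("k must be >= 2")
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    rng = np.random.default_rng(seed)
    models: dict[tuple[str, ...], ClassifierModel] = {}
    for fset in feature_sets:
        x, kept = _features_matrix(features, tuple(fset))
        y = np.array([1 if labels[p] == NEUTROPHIL else 0 for p in kept])
        if len(np.unique(y)) < 2:
            raise ValidationError("both classes must be present")
        n = len(y)
        if n < 2 * k:
            raise ValidationError(f"need >= 2 samples per fold (n={n}, k={k})")
        accs = np.zeros(n_iter)
        for it in range(n_iter):
            fold = rng.permutation(np.arange(n) % k)
            correct, total = 0, 0
            for f_id in range(k):
                test = fold == f_id
                train = ~test
                if len(np.unique(y[train])) < 2:
                    continue
                try:
                    params = _fit_logit(x[train], y[train])
                except ValidationError:
                    continue
                lp_train = params[0] + x[train] @ params[1:]
                cutoff = _youden_cutoff(lp_train, y[train])
                lp_test = params[0] + x[test] @ params[1:]
                correct += ((lp_test > cutoff).astype(int) == y[test]).sum()
                total += test.sum()
            accs[it] = correct / total if total else np.nan
        params = _fit_logit(x, y)
        lp = params[0] + x @ params[1:]
        cutoff = _youden_cutoff(lp, y)
        models[tuple(fset)] = ClassifierModel(
            intercept=float(params[0]),
            slopes={name: float(s) for name, s in zip(fset, params[1:])},
            decision_cutoff=cutoff,
            feature_set=tuple(fset),
            cv_summary={
                "k": k,
                "n_iter": n_iter,
                "mean_accuracy": float(np.nanmean(accs)),
                "sd_accuracy": float(np.nanstd(accs)),
                "n_patients": n,
            },
        )
    best = max(models, key=lambda fs: models[fs].cv_summary["mean_accuracy"])
    return models, best


def k_stability(
    features: list[PatientFeatures],
    labels: dict[str, str] | pd.Series,
    feature_set: tuple[str, ...] = ("dNeu",),
    ks: tuple[int, ...] = (3, 5, 10),
    n_iter: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """CV accuracy of one feature set across a grid of fold counts.

    Shows how stable the model is to the train/test split size; one row
    per k with the mean and sd of held-out accuracy.
    """
    rows = []
    for i, k in enumerate(ks):
        models, _ = fit_classifier(
            features, labels, feature_sets=[feature_set], k=k, n_iter=n_iter,
            seed=None if seed is None else seed + i,
        )
        cv = models[tuple(feature_set)].cv_summary
        rows.append({"k": k, "mean_accuracy": cv["mean_accuracy"],
                     "sd_accuracy": cv["sd_accuracy"]})
    return pd.DataFrame(rows).set_index("k")


def reference_model() -> ClassifierModel:
    """The published single-feature model: f(x) = 0.3438 + 1.9848*x on dNeu.

    A patient is neutrophil-driven when f(x) > 0.18 and lymphocyte-driven
    otherwise.  Constants are fixed; this model is never refit.
    """
    return ClassifierModel(
        intercept=0.3438,
        slopes={"dNeu": 1.9848},
        decision_cutoff=0.18,
        feature_set=("dNeu",),
        cv_summary={"source": "published reference model"},
    )


def classify_patient(
    model: ClassifierModel, f: PatientFeatures
) -> tuple[str, float]:
    """Label one patient: neutrophil-driven iff the linear predictor > cutoff."""
    lp = model.linear_predictor(f)
    label = NEUTROPHIL if lp > model.decision_cutoff else LYMPHOCYTE
    return label, lp


def roc_auc(predictors: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC by the rank (Mann-Whitney) formulation.

    ``labels`` are 0/1 with 1 the positive class; ties in the predictor are
    handled with midranks.  ROC points are computed at every unique
    threshold.
    """
    predictors = np.asarray(predictors, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC requires both classes present")
    ranks = rankdata(predictors)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    points = []
    for t in np.concatenate(([np.inf], np.unique(predictors)[::-1], [-np.inf])):
        pred = predictors >= t
        points.append(
            {
                "threshold": t,
                "tpr": (pred & (labels == 1)).sum() / n_pos,
                "fpr": (pred & (labels == 0)).sum() / n_neg,
            }
        )
    return pd.DataFrame(points), float(auc)
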