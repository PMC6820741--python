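"""Per-cohort nephritis odds ratios and their random-effects combination.

Each cohort contributes a 2x2 table of nephritis (yes/no) by predicted
subgroup, with the neutrophil-driven subgroup as the exposure.  The odds
ratio is (a*d)/(b*c) with the Haldane-Anscombe 0.5 continuity correction
when any cell is zero.  Cohorts are combined on the log-OR scale with the
DerSimonian-Laird random-effects estimator (inverse-variance weights
1/(SE^2 + tau^2)); an iterative Paule-Mandel tau^2 is available behind a
flag.  A leave-one-out sensitivity table shows how each cohort moves the
combined estimate and its p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError

Z95 = norm.ppf(0.975)


@dataclass
class CohortOR:
    cohort_id: str
    counts: np.ndarray  # [[neph&neut, neph&lym], [noneph&neut, noneph&lym]]
    log_or: float
    se: float
    ci_low: float
    ci_high: float
    corrected: bool

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.log_or))


@dataclass
class MetaResult:
    combined_or: float
    ci_low: float
    ci_high: float
    p: float
    tau2: float
    i2: float
    weights: pd.Series  # per cohort, sums to 1
    leave_one_out: pd.DataFrame = field(default_factory=pd.DataFrame)
    method: str = "dl"


def cohort_or(counts, cohort_id: str = "") -> CohortOR:
    """Odds ratio and CI from a 2x2 count table.

    ``counts`` is [[a, b], [c, d]] with rows nephritis yes/no and columns
    neutrophil-/lymphocyte-driven; OR = (a*d)/(b*c).  A zero anywhere adds
    0.5 to all four cells (flagged); an all-zero row or column margin is an
    error.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError("counts must be a 2x2 table")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValidationError("counts must be non-negative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValidationError("a 2x2 margin is all zero; OR undefined")
    corrected = bool(np.any(arr == 0))
    work = arr + 0.5 if corrected else arr
    a, b, c, d = work.ravel()
    log_or = float(np.log(a * d / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return CohortOR(
        cohort_id=cohort_id,
        counts=arr.astype(int),
        log_or=log_or,
        se=se,
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        corrected=corrected,
    )


def _tau2_dl(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu_fe) ** 2)
    df = len(y) - 1
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return float(max(0.0, (q - df) / c)) if c > 0 else 0.0


def _tau2_pm(y: np.ndarray, v: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> float:
    """Iterative (Paule-Mandel) tau^2: solve Q_gen(tau^2) = k - 1."""
    tau2 = _tau2_dl(y, v)
    df = len(y) - 1
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        q = np.sum(w * (y - mu) ** 2)
        num = q - df
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        step = num / denom if denom > 0 else 0.0
        new = max(0.0, tau2 + step)
        if abs(new - tau2) < tol:
            return float(new)
        tau2 = new
    return float(tau2)


def random_effects_meta(cohorts: list[CohortOR], method: str = "dl") -> MetaResult:
    """Random-effects combination of per-cohort log odds ratios.

    With one cohort the result is a flagged pass-through.  ``method`` is
    ``"dl"`` (DerSimonian-Laird, closed form) or ``"pm"`` (iterative
    Paule-Mandel).  I^2 = max(0, (Q - df)/Q) * 100 quantifies the share of
    total variability due to between-cohort heterogeneity.
    """
    if not cohorts:
        raise ValidationError("no cohorts provided")
    for c in cohorts:
        if not np.isfinite(c.se) or c.se <= 0:
            raise ValidationError(f"cohort {c.cohort_id!r} has invalid SE")
    y = np.array([c.log_or for c in cohorts])
    v = np.array([c.se**2 for c in cohorts])
    ids = [c.cohort_id or f"cohort{i + 1}" for i, c in enumerate(cohorts)]
    if len(cohorts) == 1:
        c = cohorts[0]
        return MetaResult(
            combined_or=c.odds_ratio,
            ci_low=c.ci_low,
            ci_high=c.ci_high,
            p=float(2 * norm.sf(abs(c.log_or / c.se))),
            tau2=0.0,
            i2=0.0,
            weights=pd.Series([1.0], index=ids),
            method="passthrough",
        )
    estimator = {"dl": _tau2_dl, "pm": _tau2_pm}.get(method)
    if estimator is None:
        raise ValidationError(f"unknown tau^2 method {method!r}")
    tau2 = estimator(y, v)
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    se_mu = float(np.sqrt(1.0 / np.sum(w)))
    p = float(2 * norm.sf(abs(mu / se_mu)))
    # heterogeneity from the fixed-effect Q
    w_fe = 1.0 / v
    mu_fe = np.sum(w_fe * y) / np.sum(w_fe)
    q = float(np.sum(w_fe * (y - mu_fe) ** 2))
    df = len(y) - 1
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0

    loo_rows = []
    if len(cohorts) > 2:
        for i, cid in enumerate(ids):
            rest = [c for j, c in enumerate(cohorts) if j != i]
            sub = random_effects_meta(rest, method=method)
            loo_rows.append(
                {"left_out": cid, "combined_or": sub.combined_or, "p": sub.p}
            )
    elif len(cohorts) == 2:
        for i, cid in enumerate(ids):
            c = cohorts[1 - i]
            loo_rows.append(
                {
                    "left_out": cid,
                    "combined_or": c.odds_ratio,
                    "p": float(2 * norm.sf(abs(c.log_or / c.se))),
                }
            )
    return MetaResult(
        combined_or=float(np.exp(mu)),
        ci_low=float(np.exp(mu - Z95 * se_mu)),
        ci_high=float(np.exp(mu + Z95 * se_mu)),
        p=p,
        tau2=tau2,
        i2=i2,
        weights=pd.Series(w / w.sum(), index=ids),
        leave_one_out=pd.DataFrame(loo_rows),
        method=method,
    )


def cohort_tables_from_calls(
    calls: pd.DataFrame,
) -> list[CohortOR]:
    """Build per-cohort 2x2 tables from per-patient calls.

    ``calls`` needs columns cohort_id, label (neutrophil_driven /
    lymphocyte_driven) and nephritis (0/1).
    """
    out = []
    for cohort, grp in calls.groupby("cohort_id"):
        neut = grp["label"] == "neutrophil_driven"
        neph = grp["nephritis"] == 1
        table = [
            [int((neph & neut).sum()), int((neph & ~neut).sum())],
            [int((~neph & neut).sum()), int((~neph & ~neut).sum())],
        ]
        out.append(cohort_or(table, cohort_id=str(cohort)))
    return out
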