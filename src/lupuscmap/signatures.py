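"""Per-patient and per-cluster disease signatures.

A disease signature is the pair of the most over- and under-expressed gene
sets of a patient (or patient cluster) relative to healthy controls.
Patient signatures come from fold changes against the control mean;
cluster signatures come from gene-wise two-group differential expression,
optionally combined across two cohorts by the conservative max-p rule.

All fold changes are differences on the log2 scale.  Every ranking in this
module breaks ties deterministically, falling back to lexicographic gene-id
order, so repeated runs give identical signatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ClinicalTable, ExpressionMatrix, GeneSignature
from .errors import ValidationError


@dataclass
class FoldChangeVector:
    """Per-gene log2 fold change of one case sample vs the control mean."""

    gene_ids: list[str]
    lfc: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.lfc = np.asarray(self.lfc, dtype=float)
        if len(self.gene_ids) != len(self.lfc):
            raise ValidationError("gene_ids and lfc lengths differ")
        if not np.all(np.isfinite(self.lfc)):
            raise ValidationError("fold changes must be finite")


@dataclass
class DEResult:
    """Gene-wise two-group differential expression (pooled-variance t)."""

    gene_ids: list[str]
    effect: np.ndarray
    t: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        for name in ("effect", "t", "p"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.gene_ids) == len(self.effect) == len(self.t) == len(self.p)):
            raise ValidationError("DEResult field lengths differ")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValidationError("p-values must lie in [0, 1]")


@dataclass
class CombinedDE:
    """Two-cohort combination by per-gene maximum p-value.

    ``direction`` is +1/-1 where the cohorts agree in effect sign and 0
    for discordant genes, which are ineligible for signatures.
    """

    gene_ids: list[str]
    p_max: np.ndarray
    direction: np.ndarray
    mean_abs_effect: np.ndarray


def select_active_visit(
    clinical: ClinicalTable, sledai_min: int = 5
) -> tuple[dict[str, int], list[str]]:
    """Pick each patient's most active visit.

    Keeps, per patient, the visit with the highest SLEDAI provided that
    maximum is strictly greater than ``sledai_min``; ties go to the
    earliest qualifying visit.  Returns the mapping and the list of
    excluded patients (those never exceeding the threshold).
    """
    df = clinical.data
    if df.empty:
        raise ValidationError("clinical table is empty")
    selected: dict[str, int] = {}
    excluded: list[str] = []
    for patient, grp in df.groupby("patient_id", sort=True):
        peak = grp["sledai"].max()
        if peak <= sledai_min:
            excluded.append(str(patient))
            continue
        best = grp.loc[grp["sledai"] == peak, "visit_index"].min()
        selected[str(patient)] = int(best)
    return selected, excluded


def patient_fold_changes(expr: ExpressionMatrix) -> list[FoldChangeVector]:
    """Log2 fold change of every case sample against the mean of controls."""
    controls = expr.control_ids
    if not controls:
        raise ValidationError("fold changes require at least one control sample")
    ctrl_mean = expr.values[controls].mean(axis=1).to_numpy()
    out = []
    for case in expr.case_ids:
        lfc = expr.values[case].to_numpy() - ctrl_mean
        out.append(FoldChangeVector(gene_ids=expr.gene_ids, lfc=lfc, sample_id=case))
    return out


def extract_signature(
    fc: FoldChangeVector, n_per_side: int = 150, origin: str | None = None
) -> GeneSignature:
    """Top-``n_per_side`` over- and under-expressed genes of a fold-change vector.

    Up genes are sorted by descending fold change, down genes by ascending;
    ties break lexicographically on gene id.  The universe must be at least
    twice ``n_per_side`` so the two sides cannot collide.
    """
    n_genes = len(fc.gene_ids)
    if n_genes < 2 * n_per_side:
        raise ValidationError(
            f"universe of {n_genes} genes cannot supply two disjoint sets of {n_per_side}"
        )
    order = sorted(range(n_genes), key=lambda i: (-fc.lfc[i], fc.gene_ids[i]))
    up = [fc.gene_ids[i] for i in order[:n_per_side]]
    taken = set(up)  # ties spanning the middle must not put a gene on both sides
    rev = sorted(range(n_genes), key=lambda i: (fc.lfc[i], fc.gene_ids[i]))
    down = [fc.gene_ids[i] for i in rev if fc.gene_ids[i] not in taken][:n_per_side]
    return GeneSignature(up=up, down=down, origin=origin or fc.sample_id)


def cluster_de(expr: ExpressionMatrix, case_ids: list[str] | None = None) -> DEResult:
    """Gene-wise case-vs-control differential expression.

    Two-group linear model per gene: pooled-variance t statistic with
    n1 + n2 - 2 degrees of freedom and a two-sided p-value.  ``case_ids``
    restricts the case group (e.g. to one patient cluster).
    """
    cases = case_ids if case_ids is not None else expr.case_ids
    unknown = set(cases) - set(expr.sample_ids)
    if unknown:
        raise ValidationError(f"unknown case samples: {sorted(unknown)[:10]}")
    controls = expr.control_ids
    n1, n2 = len(cases), len(controls)
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"each group needs >= 2 samples (cases={n1}, controls={n2})"
        )
    x = expr.values[cases].to_numpy()
    y = expr.values[controls].to_numpy()
    effect = x.mean(axis=1) - y.mean(axis=1)
    sp2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n1 + n2 - 2)
    return DEResult(gene_ids=expr.gene_ids, effect=effect, t=t, p=np.minimum(p, 1.0))


def combine_max_p(a: DEResult, b: DEResult) -> CombinedDE:
    """Combine two cohorts' DE results by the per-gene maximum p-value.

    Runs on the gene intersection.  A gene's direction is set only when the
    two effect estimates agree in sign; discordant genes get direction 0
    and are excluded from signature eligibility.
    """
    ia = {g: i for i, g in enumerate(a.gene_ids)}
    common = [g for g in b.gene_ids if g in ia]
    if not common:
        raise ValidationError("cohort DE results share no genes")
    ib = {g: i for i, g in enumerate(b.gene_ids)}
    ax = np.array([ia[g] for g in common])
    bx = np.array([ib[g] for g in common])
    p_max = np.maximum(a.p[ax], b.p[bx])
    sign_a, sign_b = np.sign(a.effect[ax]), np.sign(b.effect[bx])
    direction = np.where((sign_a == sign_b) & (sign_a != 0), sign_a, 0.0)
    mean_abs = (np.abs(a.effect[ax]) + np.abs(b.effect[bx])) / 2.0
    return CombinedDE(
        gene_ids=common, p_max=p_max, direction=direction, mean_abs_effect=mean_abs
    )


def cluster_signature(
    c: CombinedDE, n_per_side: int = 150, origin: str = "cluster"
) -> GeneSignature:
    """Top significant genes per direction of a combined DE result.

    Within each direction genes rank by ascending max-p, ties by descending
    mean absolute effect, then lexicographically.
    """
    df = pd.DataFrame(
        {
            "gene": c.gene_ids,
            "p": c.p_max,
            "dir": c.direction,
            "eff": c.mean_abs_effect,
        }
    )
    sides = {}
    for label, sign in (("up", 1), ("down", -1)):
        sub = df[df["dir"] == sign].sort_values(
            ["p", "eff", "gene"], ascending=[True, False, True]
        )
        if len(sub) < n_per_side:
            raise ValidationError(
                f"only {len(sub)} concordant {label} genes, need {n_per_side}"
            )
        sides[label] = list(sub["gene"].head(n_per_side))
    return GeneSignature(up=sides["up"], down=sides["down"], origin=origin)
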