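"""Mechanism-of-action (MOA) and drug-target matrix algebra.

Cluster-level connectivity scores are aggregated into MOA space by
multiplying the clusters x drugs connectivity matrix with a binary
drugs x MOA membership matrix; coefficients with |value| >= 90 are flagged
as significant.  The same product pattern maps binary drug-target tables
through a target x blood-cell-type expression table to show in which cell
types each drug's targets are expressed.  MOA similarity for a single drug
is assessed by weighted-KS enrichment of each MOA's member drugs within a
drug-similarity ranking, with a permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import weighted_ks_es
from .core_io import RankedProfile
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MOAMatrix:
    values: pd.DataFrame  # clusters x MOA
    mask: pd.DataFrame  # significance |value| >= threshold
    threshold: float


@dataclass
class MOAEnrichment:
    es: pd.Series  # per MOA, signed
    p: pd.Series
    significant: list[str]
    skipped: list[str] = field(default_factory=list)


def _align(left: pd.DataFrame, right: pd.DataFrame, what: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    common = left.columns.intersection(right.index)
    if len(common) == 0:
        raise ValidationError(f"no shared {what} between the two matrices")
    lost = len(left.columns) - len(common)
    if lost or len(right.index) != len(common):
        logger.info(
            "%s alignment dropped %d/%d left and %d/%d right ids",
            what, lost, len(left.columns),
            len(right.index) - len(common), len(right.index),
        )
    return left[common], right.loc[common]


def cluster_moa(
    cluster_conn: pd.DataFrame,
    drug_moa: pd.DataFrame,
    threshold: float = 90.0,
    normalize: bool = False,
) -> MOAMatrix:
    """Clusters x MOA matrix from connectivity scores and MOA membership.

    Plain matrix product over the shared drugs; with ``normalize=True``
    each MOA column is divided by its member count (mean instead of sum),
    removing the advantage large MOAs get from raw summation.
    """
    conn, moa = _align(cluster_conn, drug_moa, "drug")
    values = conn.to_numpy(dtype=float) @ moa.to_numpy(dtype=float)
    out = pd.DataFrame(values, index=cluster_conn.index, columns=moa.columns)
    if normalize:
        sizes = moa.sum(axis=0).replace(0, np.nan)
        out = out / sizes
        out = out.fillna(0.0)
    mask = out.abs() >= threshold
    return MOAMatrix(values=out, mask=mask, threshold=threshold)


def drug_celltype(
    drug_target: pd.DataFrame,
    target_expr: pd.DataFrame,
    normalize_rows: bool = False,
) -> pd.DataFrame:
    """Drugs x cell-type matrix: binary drug-target table times target expression."""
    dt, te = _align(drug_target, target_expr, "target")
    values = dt.to_numpy(dtype=float) @ te.to_numpy(dtype=float)
    out = pd.DataFrame(values, index=drug_target.index, columns=te.columns)
    if normalize_rows:
        sums = out.abs().sum(axis=1).replace(0, np.nan)
        out = out.div(sums, axis=0).fillna(0.0)
    return out


def moa_similarity_gsea(
    query_drug: str,
    library_similarity: pd.Series,
    drug_moa: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    weight_exp: float = 1.0,
    seed: int | None = None,
) -> MOAEnrichment:
    """Which MOAs are enriched among the drugs most similar to a query drug.

    ``library_similarity`` holds a similarity score per drug, ranked
    descending to form the "profile"; each MOA's member drugs act as the
    gene set in a weighted-KS enrichment with |similarity| as the weight
    statistic.  p-values come from permuting drug positions ``n_perm``
    times (add-one estimator); MOAs with p <= ``alpha`` are significant.
    MOAs with fewer than 2 member drugs in the ranking are skipped.
    """
    sims = library_similarity.sort_values(ascending=False)
    ranking = RankedProfile(genes=list(sims.index.map(str)), stats=sims.to_numpy())
    rng = np.random.default_rng(seed)
    n = len(ranking.genes)
    es_vals, p_vals, skipped = {}, {}, []
    for moa_id in drug_moa.columns:
        members = [str(d) for d in drug_moa.index[drug_moa[moa_id] == 1]]
        present = [d for d in members if d in set(ranking.genes)]
        if len(present) < 2:
            skipped.append(moa_id)
            logger.warning("MOA %s skipped: %d member drug(s) in ranking", moa_id, len(present))
            continue
        obs = weighted_ks_es(present, ranking, weight_exp)
        count = 0
        size = len(present)
        for _ in range(n_perm):
            perm = [ranking.genes[i] for i in rng.choice(n, size=size, replace=False)]
            null_es = weighted_ks_es(perm, ranking, weight_exp)
            if abs(null_es) >= abs(obs):
                count += 1
        es_vals[moa_id] = obs
        p_vals[moa_id] = (1.0 + count) / (n_perm + 1.0)
    es = pd.Series(es_vals, name="es", dtype=float)
    p = pd.Series(p_vals, name="p", dtype=float)
    significant = list(p.index[p <= alpha])
    return MOAEnrichment(es=es, p=p, significant=significant, skipped=skipped)
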