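"""Consensus clustering of patient connectivity profiles and subgroup statistics.

Patients are clustered on their drug-connectivity score profiles with a
resampling consensus procedure: repeatedly subsample both drugs (features)
and patients (items), cluster the subsample hierarchically (1 - Pearson
correlation distance, average linkage), and record for every patient pair
the fraction of co-samplings in which they co-clustered.  The number of
clusters is chosen by the delta-area rule on the consensus CDF.

``nlr_subgroup_stats`` compares the resulting subgroups on the
neutrophil-to-lymphocyte ratio (NLR) at the active visit and on dNLR, the
per-patient correlation of NLR with SLEDAI across visits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import f_oneway, pearsonr
from sklearn.metrics import adjusted_rand_score

from .core_io import ClinicalTable
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]  # k -> patients x patients in [0,1]
    labels: dict[int, pd.Series]  # k -> hard labels in 1..k
    chosen_k: int
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    params: dict = field(default_factory=dict)


@dataclass
class SubgroupStats:
    per_patient: pd.DataFrame  # patient_id, subgroup, nlr, dnlr
    group_means: pd.DataFrame  # subgroup x {nlr, dnlr}
    anova: dict[str, tuple[float, float]]  # metric -> (F, p)
    excluded: list[str] = field(default_factory=list)


def _corr_distance(columns: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between the columns of a matrix."""
    c = np.corrcoef(columns.T)
    c = np.clip(np.nan_to_num(c, nan=0.0), -1.0, 1.0)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def consensus_cluster(
    m: pd.DataFrame,
    k_range: range | list[int] = range(2, 7),
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    seed: int | None = None,
) -> ConsensusResult:
    """Resampling consensus clustering of the columns (patients) of ``m``.

    Each resample draws ``subsample_frac`` of the patients and of the drugs
    without replacement, clusters the subsampled patient profiles by
    average-linkage hierarchical clustering at each k, and accumulates
    co-clustering counts.  consensus(i, j) is the co-cluster count divided
    by the co-sampling count.  Final labels at each k come from clustering
    1 - consensus; ``chosen_k`` maximizes the delta-area criterion of the
    consensus CDF.
    """
    ks = sorted(set(int(k) for k in k_range))
    n_pat = m.shape[1]
    n_drugs = m.shape[0]
    if n_pat < 6:
        raise ValidationError("consensus clustering needs >= 6 patients")
    if max(ks) >= n_pat:
        raise ValidationError(f"k_range max {max(ks)} must be < n_patients {n_pat}")
    arr = m.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("connectivity matrix must be complete and finite")
    rng = np.random.default_rng(seed)
    n_sub_p = max(2, int(np.ceil(subsample_frac * n_pat)))
    n_sub_d = max(2, int(np.ceil(subsample_frac * n_drugs)))

    co_cluster = {k: np.zeros((n_pat, n_pat)) for k in ks}
    co_sample = np.zeros((n_pat, n_pat))
    for _ in range(n_resamples):
        pats = rng.choice(n_pat, size=n_sub_p, replace=False)
        drugs = rng.choice(n_drugs, size=n_sub_d, replace=False)
        sub = arr[np.ix_(drugs, pats)]
        dist = _corr_distance(sub)
        z = linkage(dist, method="average")
        co_sample[np.ix_(pats, pats)] += 1
        for k in ks:
            lab = fcluster(z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_cluster[k][np.ix_(pats, pats)] += same

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = {
            k: np.where(co_sample > 0, co_cluster[k] / co_sample, 0.0) for k in ks
        }
    patients = list(m.columns)
    cons_df, labels = {}, {}
    area, delta = {}, {}
    prev_area = None
    for k in ks:
        c = consensus[k]
        c = (c + c.T) / 2.0
        np.fill_diagonal(c, 1.0)
        cons_df[k] = pd.DataFrame(c, index=patients, columns=patients)
        z = linkage(squareform(1.0 - c, checks=False), method="average")
        labels[k] = pd.Series(
            fcluster(z, t=k, criterion="maxclust"), index=patients, name="cluster"
        )
        # area under the empirical CDF of the off-diagonal consensus values
        vals = np.sort(c[np.triu_indices(n_pat, k=1)])
        cdf = np.arange(1, len(vals) + 1) / len(vals)
        grid = np.concatenate(([0.0], vals, [1.0]))
        cdf_g = np.concatenate(([0.0], cdf, [1.0]))
        a = float(np.trapezoid(cdf_g, grid))
        area[k] = a
        delta[k] = a if prev_area is None else (a - prev_area) / prev_area
        prev_area = a

    chosen_k = max(ks, key=lambda k: delta[k])
    return ConsensusResult(
        consensus=cons_df,
        labels=labels,
        chosen_k=chosen_k,
        cdf_area=area,
        delta_area=delta,
        params={
            "n_resamples": n_resamples,
            "subsample_frac": subsample_frac,
            "seed": seed,
            "k_range": ks,
        },
    )


def crosstab_labels(a: pd.Series, b: pd.Series) -> tuple[pd.DataFrame, float]:
    """Contingency table and adjusted Rand index of two patient labelings."""
    if set(a.index) != set(b.index):
        raise ValidationError("labelings cover different patient sets")
    b = b.reindex(a.index)
    table = pd.crosstab(a, b)
    ari = float(adjusted_rand_score(a.to_numpy(), b.to_numpy()))
    return table, ari


def nlr_subgroup_stats(
    clinical: ClinicalTable,
    labels: pd.Series,
    active_visits: dict[str, int],
) -> SubgroupStats:
    """NLR and dNLR per patient and their one-way ANOVA across subgroups.

    NLR is neut%/lymph% at the active visit; dNLR the Pearson correlation
    of the per-visit NLR with SLEDAI.  Patients with zero lymphocytes at
    the active visit, or with degenerate (constant) series, are excluded
    from the corresponding comparison and reported.
    """
    missing = set(labels.index) - set(clinical.patient_ids)
    if missing:
        raise ValidationError(f"labels reference unknown patients: {sorted(missing)[:10]}")
    rows, excluded = [], []
    for patient, grp in clinical.data.groupby("patient_id"):
        patient = str(patient)
        if patient not in labels.index:
            continue
        nlr_val = np.nan
        if patient in active_visits:
            visit = grp[grp["visit_index"] == active_visits[patient]]
            if len(visit) == 1:
                lymph = float(visit["lymph_pct"].iloc[0])
                if lymph > 0:
                    nlr_val = float(visit["neut_pct"].iloc[0]) / lymph
                else:
                    excluded.append(patient)
                    logger.info("patient %s: lymph%% = 0 at active visit", patient)
        dnlr = np.nan
        ok = grp["lymph_pct"] > 0
        if ok.sum() >= 3:
            series = grp.loc[ok, "neut_pct"] / grp.loc[ok, "lymph_pct"]
            sledai = grp.loc[ok, "sledai"].astype(float)
            if series.nunique() > 1 and sledai.nunique() > 1:
                dnlr = float(pearsonr(series, sledai)[0])
        rows.append(
            {
                "patient_id": patient,
                "subgroup": labels.loc[patient],
                "nlr": nlr_val,
                "dnlr": dnlr,
            }
        )
    per_patient = pd.DataFrame(rows).set_index("patient_id")
    anova = {}
    for metric in ("nlr", "dnlr"):
        groups = [
            g[metric].dropna().to_numpy()
            for _, g in per_patient.groupby("subgroup")
        ]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) >= 2:
            f, p = f_oneway(*groups)
            anova[metric] = (float(f), float(p))
        else:
            anova[metric] = (np.nan, np.nan)
    group_means = per_patient.groupby("subgroup")[["nlr", "dnlr"]].mean()
    return SubgroupStats(
        per_patient=per_patient, group_means=group_means, anova=anova, excluded=excluded
    )
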