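"""Local connectivity-map scoring engine.

Scores disease signatures against a library of drug perturbation profiles
using the weighted Kolmogorov-Smirnov enrichment statistic and the WTCS /
NCS / tau conventions of the Connectivity Map:

* ``weighted_ks_es`` — signed enrichment score of a gene set against one
  ranked profile (hits weighted by |statistic|^w, misses by the uniform
  miss penalty).
* ``wtcs`` — weighted total connectivity score of an up/down signature:
  the mean of the two enrichment scores when their signs disagree, else 0.
* ``normalize_and_tau`` — per-drug sign-stratified normalization against a
  reference ("touchstone") panel, then signed percentile scaling to the
  tau scale [-100, 100].
* ``absolute_rank_sum_select`` — permutation test retaining drugs that
  score consistently strong in absolute value across patients.
* ``significant_drugs`` — the inclusive |tau| >= 90 filter used for
  cluster-level queries.

Strongly negative tau means the drug profile reverses the disease
signature, the property drug repurposing looks for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import percentileofscore

from .core_io import DrugLibrary, GeneSignature, RankedProfile
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ConnectivityMatrix:
    """Drugs x queries score matrix tagged with its processing stage."""

    values: pd.DataFrame  # drugs on the index, queries on the columns
    stage: str  # "wtcs" | "ncs" | "tau"

    def __post_init__(self) -> None:
        if self.stage not in {"wtcs", "ncs", "tau"}:
            raise ValidationError(f"unknown stage {self.stage!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("connectivity scores must be finite")
        if self.stage == "wtcs" and np.any(np.abs(arr) > 1 + 1e-9):
            raise ValidationError("WTCS values must lie in [-1, 1]")
        if self.stage == "tau" and np.any(np.abs(arr) > 100 + 1e-9):
            raise ValidationError("tau values must lie in [-100, 100]")


@dataclass
class RankSumSelection:
    """Result of the absolute-rank-sum drug selection."""

    retained: list[str]
    statistic: pd.Series  # per-drug sum of within-patient |tau| ranks
    p: pd.Series
    alpha: float


def weighted_ks_es(
    gene_set: Sequence[str],
    profile: RankedProfile,
    weight_exp: float = 1.0,
) -> float:
    """Signed weighted-KS enrichment score of ``gene_set`` in ``profile``.

    Walking down the ranking, a hit advances the running sum by its
    normalized weight |stat|^weight_exp / sum over hits, a miss retreats it
    by 1/(N - |S|).  The score is the running-sum value of maximum absolute
    deviation, so it lies in [-1, 1]: positive when the set concentrates at
    the top of the ranking, negative at the bottom.

    Set genes absent from the universe are dropped with a warning; an empty
    set, a set spanning the whole universe, or a set with no gene in the
    universe is an error.
    """
    if len(gene_set) == 0:
        raise ValidationError("gene set is empty")
    pos = getattr(profile, "_pos", None)
    if pos is None or len(pos) != len(profile.genes):
        pos = {g: i for i, g in enumerate(profile.genes)}
        profile._pos = pos  # cache: profiles are effectively immutable
    present = [g for g in gene_set if g in pos]
    dropped = len(gene_set) - len(present)
    if dropped:
        logger.warning("%d gene(s) of the set absent from the profile universe", dropped)
    if not present:
        raise ValidationError("no gene of the set occurs in the profile universe")
    n = len(profile.genes)
    n_hit = len(present)
    if n_hit == n:
        raise ValidationError("gene set equals the universe; miss penalty undefined")
    hit_idx = np.fromiter((pos[g] for g in present), dtype=np.intp, count=n_hit)
    steps = np.full(n, -1.0 / (n - n_hit))
    if weight_exp == 0:
        weights = np.ones(n_hit)
    else:
        weights = np.abs(profile.stats[hit_idx]) ** weight_exp
    total = weights.sum()
    if total == 0:  # all-zero statistic at the hits: fall back to unweighted
        weights = np.ones(n_hit)
        total = float(n_hit)
    steps[hit_idx] = weights / total
    runsum = np.cumsum(steps)
    return float(runsum[np.argmax(np.abs(runsum))])


def wtcs(
    sig: GeneSignature,
    profile: RankedProfile,
    weight_exp: float = 1.0,
    min_coverage: float = 0.9,
) -> float:
    """Weighted total connectivity score of a signature against a profile.

    The up and down enrichment scores are averaged as (ES_up - ES_dn)/2
    when they disagree in sign; a sign match means the profile does not
    discriminate the two sides and the score is 0.
    """
    universe = set(profile.genes)
    sig_genes = list(sig.up) + list(sig.down)
    covered = sum(g in universe for g in sig_genes)
    if covered < min_coverage * len(sig_genes):
        missing = [g for g in sig_genes if g not in universe]
        raise ValidationError(
            f"profile covers {covered}/{len(sig_genes)} signature genes "
            f"(< {min_coverage:.0%}); missing e.g. {missing[:10]}"
        )
    es_up = weighted_ks_es(sig.up, profile, weight_exp)
    es_dn = weighted_ks_es(sig.down, profile, weight_exp)
    if np.sign(es_up) == np.sign(es_dn):
        return 0.0
    return (es_up - es_dn) / 2.0


def score_library(
    signatures: Sequence[GeneSignature],
    library: DrugLibrary,
    weight_exp: float = 1.0,
) -> ConnectivityMatrix:
    """WTCS of every signature (column) against every library drug (row)."""
    cols = {}
    for sig in signatures:
        name = sig.origin or f"query{len(cols)}"
        cols[name] = [
            wtcs(sig, library.profiles[d], weight_exp) for d in library.drug_ids
        ]
    values = pd.DataFrame(cols, index=library.drug_ids)
    return ConnectivityMatrix(values=values, stage="wtcs")


def normalize_and_tau(
    raw: ConnectivityMatrix, reference: ConnectivityMatrix, min_reference: int = 20
) -> ConnectivityMatrix:
    """Normalize raw WTCS per drug and rescale to the tau percentile scale.

    NCS divides each WTCS by the drug's mean |WTCS| over same-sign
    reference entries (drugs with no same-sign reference score get NCS 0,
    logged).  tau(d, q) is the signed percentile rank of |NCS(d, q)| among
    the drug's reference |NCS| values, in [-100, 100]: tau near +/-100
    means the query connects to the drug more strongly than essentially
    the whole reference panel.
    """
    if raw.stage != "wtcs" or reference.stage != "wtcs":
        raise ValidationError("normalize_and_tau expects wtcs-stage matrices")
    ref = reference.values.reindex(index=raw.values.index)
    if ref.isna().any().any():
        raise ValidationError("reference matrix missing drugs present in raw matrix")
    if ref.shape[1] < min_reference:
        raise ValidationError(
            f"reference needs >= {min_reference} queries, got {ref.shape[1]}"
        )

    def _ncs_row(row: np.ndarray, ref_row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        out = np.zeros_like(row)
        ref_out = np.zeros_like(ref_row)
        for sign in (1.0, -1.0):
            same = ref_row * sign > 0
            denom = np.abs(ref_row[same]).mean() if same.any() else 0.0
            sel = row * sign > 0
            if denom > 0:
                out[sel] = row[sel] / denom
                ref_out[same] = ref_row[same] / denom
            elif sel.any():
                logger.info("drug has no same-sign reference scores; NCS set to 0")
        return out, ref_out

    tau = np.zeros(raw.values.shape)
    raw_arr = raw.values.to_numpy(dtype=float)
    ref_arr = ref.to_numpy(dtype=float)
    for i in range(raw_arr.shape[0]):
        ncs_row, ncs_ref = _ncs_row(raw_arr[i], ref_arr[i])
        abs_ref = np.abs(ncs_ref)
        for j, v in enumerate(ncs_row):
            if v == 0:
                continue
            pct = percentileofscore(abs_ref, abs(v), kind="mean")
            tau[i, j] = np.sign(v) * pct
    values = pd.DataFrame(tau, index=raw.values.index, columns=raw.values.columns)
    return ConnectivityMatrix(values=values, stage="tau")


def absolute_rank_sum_select(
    conn: ConnectivityMatrix,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> RankSumSelection:
    """Retain drugs consistently strong in |score| across patients.

    Within each patient column drugs are ranked by descending |tau|
    (rank 1 = strongest); the statistic is the rank sum across patients,
    small when a drug is near the top for most patients.  The null
    distribution permutes ranks independently within each patient; the
    permutation p-value uses the add-one estimator so it can never be 0.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100 for a usable permutation p")
    values = conn.values
    n_drugs, n_pat = values.shape
    if n_pat < 2:
        raise ValidationError("rank-sum selection needs >= 2 patients")
    abs_scores = np.abs(values.to_numpy(dtype=float))
    # rank 1 = largest |score|, average ranks on ties
    ranks = pd.DataFrame(abs_scores).rank(axis=0, ascending=False, method="average")
    observed = ranks.to_numpy().sum(axis=1)
    rng = np.random.default_rng(seed)
    null = np.zeros((n_perm, n_drugs))
    base = ranks.to_numpy()
    for b in range(n_perm):
        cols = [base[rng.permutation(n_drugs), j] for j in range(n_pat)]
        null[b] = np.sum(cols, axis=0)
    p = (1.0 + (null <= observed[None, :]).sum(axis=0)) / (n_perm + 1.0)
    stat = pd.Series(observed, index=values.index, name="rank_sum")
    p_ser = pd.Series(p, index=values.index, name="p")
    retained = list(p_ser.index[p_ser <= alpha])
    return RankSumSelection(retained=retained, statistic=stat, p=p_ser, alpha=alpha)


def significant_drugs(
    cluster_conn: ConnectivityMatrix, threshold: float = 90.0
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Per-cluster drugs with |tau| >= threshold (inclusive), plus the union.

    Returns a mapping cluster -> retained drug ids and a drugs x clusters
    boolean membership table restricted to the union.
    """
    if cluster_conn.stage != "tau":
        raise ValidationError("significance filter requires a tau-stage matrix")
    values = cluster_conn.values
    mask = values.abs() >= threshold
    per_cluster = {c: list(values.index[mask[c]]) for c in values.columns}
    union = values.index[mask.any(axis=1)]
    return per_cluster, mask.loc[union]
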