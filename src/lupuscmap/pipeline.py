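"""End-to-end orchestration of the stratification and classification pipeline.

Glues the stage modules together the way the analysis is meant to run:
patient signatures -> connectivity scoring -> rank-sum drug selection ->
consensus clustering -> cluster signatures (max-p combined across two
cohorts) -> |tau| >= 90 drug selection -> MOA algebra, plus the clinical
classifier train/test split and the nephritis meta-analysis.  The entry
point ``run_synthetic_pipeline`` exercises all of it on generated cohorts
and reports recovery metrics against the planted ground truth.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import classify, connectivity, meta, moa, signatures, stratify, synthetic
from .classify import LYMPHOCYTE, NEUTROPHIL
from .core_io import DrugLibrary, ExpressionMatrix, GeneSignature
from .errors import ValidationError
from .synthetic import SimulationConfig, child_seeds

logger = logging.getLogger(__name__)


def patient_signatures(
    expr: ExpressionMatrix, n_per_side: int = 150
) -> list[GeneSignature]:
    return [
        signatures.extract_signature(fc, n_per_side=n_per_side)
        for fc in signatures.patient_fold_changes(expr)
    ]


def tau_matrix(
    sigs: list[GeneSignature],
    library: DrugLibrary,
    reference_sigs: list[GeneSignature],
) -> connectivity.ConnectivityMatrix:
    """WTCS against the library, normalized to tau via the reference panel."""
    raw = connectivity.score_library(sigs, library)
    ref = connectivity.score_library(reference_sigs, library)
    return connectivity.normalize_and_tau(raw, ref)


def drug_signature(profile, n_per_side: int = 150, origin: str = "") -> GeneSignature:
    """A drug's own top/bottom genes, used for drug-drug similarity."""
    return GeneSignature(
        up=list(profile.genes[:n_per_side]),
        down=list(profile.genes[-n_per_side:][::-1]),
        origin=origin,
    )


def drug_drug_similarity(library: DrugLibrary, n_per_side: int = 150) -> pd.DataFrame:
    """Drugs x drugs WTCS of each drug's own signature against all profiles."""
    sigs = [
        drug_signature(library.profiles[d], n_per_side, origin=d)
        for d in library.drug_ids
    ]
    return connectivity.score_library(sigs, library).values


def cluster_to_subgroup(
    labels: pd.Series, features: list[classify.PatientFeatures]
) -> dict[int, str]:
    """Name clusters by their members' mean dNeu: higher -> neutrophil-driven."""
    dneu = {f.patient_id: f.dNeu for f in features}
    means = {
        int(c): np.nanmean([dneu.get(p, np.nan) for p in labels.index[labels == c]])
        for c in labels.unique()
    }
    ranked = sorted(means, key=lambda c: means[c], reverse=True)
    mapping = {ranked[0]: NEUTROPHIL}
    for c in ranked[1:]:
        mapping[c] = LYMPHOCYTE
    return mapping


def _cohort_stage(
    cfg: SimulationConfig,
    seed: int,
    library: DrugLibrary | None,
    reference_sigs: list[GeneSignature] | None,
    n_resamples: int,
    rank_sum_perm: int,
) -> dict:
    """Simulate one cohort and run it through clustering."""
    s_clin, s_expr, s_lib, s_ref = child_seeds(seed, 4)
    clinical, truth = synthetic.simulate_clinical(cfg, s_clin)
    expr = synthetic.simulate_expression(cfg, clinical, truth, s_expr)
    if library is None:
        library = synthetic.simulate_drug_library(cfg, truth, s_lib)
    else:
        truth.reverting = {
            d: g for d, g in _library_truth(library).items()
        }
    if reference_sigs is None:
        reference_sigs = synthetic.random_signatures(
            library.gene_ids, 30, min(150, cfg.module_size_per_side), seed=s_ref
        )
    sigs = patient_signatures(expr, n_per_side=min(150, cfg.module_size_per_side))
    tau = tau_matrix(sigs, library, reference_sigs)
    selection = connectivity.absolute_rank_sum_select(
        tau, n_perm=rank_sum_perm, seed=seed
    )
    drugs = selection.retained if len(selection.retained) >= 2 else list(tau.values.index)
    if len(selection.retained) < 2:
        logger.info("rank-sum selection kept <2 drugs; clustering on all drugs")
    consensus = stratify.consensus_cluster(
        tau.values.loc[drugs], k_range=range(2, 6), n_resamples=n_resamples, seed=seed
    )
    labels = consensus.labels[2]
    truth_labels = pd.Series(
        {p: truth.subgroup[p] for p in labels.index}, name="truth"
    )
    _, ari = stratify.crosstab_labels(labels, truth_labels)
    features, _ = classify.longitudinal_features(clinical)
    mapping = cluster_to_subgroup(labels, features)
    named_labels = labels.map(mapping)
    return {
        "clinical": clinical,
        "truth": truth,
        "expr": expr,
        "library": library,
        "reference_sigs": reference_sigs,
        "tau": tau,
        "selection": selection,
        "consensus": consensus,
        "labels": named_labels,
        "ari": ari,
        "features": features,
    }


def _library_truth(library: DrugLibrary) -> dict[str, str]:
    out = {}
    for drug in library.drug_ids:
        if drug.startswith("rev_neutrophil"):
            out[drug] = NEUTROPHIL
        elif drug.startswith("rev_lymphocyte"):
            out[drug] = LYMPHOCYTE
    return out


def run_synthetic_pipeline(
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    n_resamples: int = 200,
    rank_sum_perm: int = 500,
    cv_iters: int = 50,
    cv_k: int = 5,
    moa_perm: int = 500,
    n_meta_cohorts: int = 4,
) -> dict:
    """Two synthetic cohorts through the full pipeline; recovery metrics out."""
    cfg = cfg or SimulationConfig()
    s_a, s_b, s_cls, s_meta = child_seeds(seed, 4)
    cfg_a = dataclasses.replace(cfg, cohort_id="sim1")
    cfg_b = dataclasses.replace(cfg, cohort_id="sim2")
    coh_a = _cohort_stage(cfg_a, s_a, None, None, n_resamples, rank_sum_perm)
    coh_b = _cohort_stage(
        cfg_b, s_b, coh_a["library"], coh_a["reference_sigs"], n_resamples, rank_sum_perm
    )
    library: DrugLibrary = coh_a["library"]
    n_side = min(150, cfg.module_size_per_side)

    # --- cluster signatures, combined across the two cohorts by max-p
    cluster_sigs: list[GeneSignature] = []
    for group in (NEUTROPHIL, LYMPHOCYTE):
        de = {}
        for tag, coh in (("a", coh_a), ("b", coh_b)):
            members = [p for p, lab in coh["labels"].items() if lab == group]
            de[tag] = signatures.cluster_de(coh["expr"], case_ids=members)
        combined = signatures.combine_max_p(de["a"], de["b"])
        cluster_sigs.append(
            signatures.cluster_signature(combined, n_per_side=n_side, origin=group)
        )

    cluster_tau = tau_matrix(cluster_sigs, library, coh_a["reference_sigs"])
    per_cluster, membership = connectivity.significant_drugs(cluster_tau)

    # --- MOA algebra on the cluster-level connectivity
    moa_matrix = moa.cluster_moa(cluster_tau.values.T, library.moa)
    sim = drug_drug_similarity(library, n_per_side=n_side)
    union = list(membership.index)
    moa_enrich = {}
    for drug in union[:10]:  # cap the per-drug GSEA loop at a handful of queries
        moa_enrich[drug] = moa.moa_similarity_gsea(
            drug, sim[drug], library.moa, n_perm=moa_perm, seed=s_meta
        )

    # --- reverting-drug recovery through the connectivity engine
    truth_a = coh_a["truth"]
    rev_taus = []
    for drug, group in truth_a.reverting.items():
        rev_taus.append(float(cluster_tau.values.loc[drug, group]))
    rev_taus = np.array(rev_taus)

    # --- classifier: train on a larger clinical-only cohort (its subgroup
    # labels play the role of the externally supplied longitudinal clusters),
    # then test on cohort B against the planted truth
    s_train, s_fit = child_seeds(s_cls, 2)
    cfg_train = dataclasses.replace(
        cfg, cohort_id="train", n_per_subgroup=cfg.n_clinical_per_subgroup
    )
    clin_train, truth_train = synthetic.simulate_clinical(cfg_train, s_train)
    feats_train, _ = classify.longitudinal_features(clin_train)
    labels_train = {f.patient_id: truth_train.subgroup[f.patient_id] for f in feats_train}
    feats_b = coh_b["features"]
    models, best = classify.fit_classifier(
        feats_train,
        labels_train,
        feature_sets=[("dNeu",), ("dLym",), ("dNLR",)],
        k=cv_k,
        n_iter=cv_iters,
        seed=s_fit,
    )
    model = models[best]
    truth_b = coh_b["truth"].subgroup
    predictors, y = [], []
    for f in feats_b:
        try:
            predictors.append(model.linear_predictor(f))
        except ValidationError:
            continue
        y.append(1 if truth_b[f.patient_id] == NEUTROPHIL else 0)
    _, auc = classify.roc_auc(np.array(predictors), np.array(y))

    # --- nephritis meta-analysis over several clinical-only cohorts
    cohort_ors = []
    for i, ms in enumerate(child_seeds(s_meta, n_meta_cohorts)):
        cfg_m = dataclasses.replace(
            cfg, cohort_id=f"meta{i + 1}", n_per_subgroup=cfg.n_clinical_per_subgroup
        )
        clin_m, _ = synthetic.simulate_clinical(cfg_m, ms)
        feats_m, _ = classify.longitudinal_features(clin_m)
        calls = []
        neph = clin_m.data.groupby("patient_id")["nephritis"].first()
        for f in feats_m:
            label, _ = classify.classify_patient(classify.reference_model(), f)
            calls.append(
                {
                    "cohort_id": cfg_m.cohort_id,
                    "label": label,
                    "nephritis": int(neph[f.patient_id]),
                }
            )
        tables = meta.cohort_tables_from_calls(pd.DataFrame(calls))
        cohort_ors.extend(tables)
    meta_result = meta.random_effects_meta(cohort_ors)

    return {
        "cohort_a": coh_a,
        "cohort_b": coh_b,
        "cluster_signatures": cluster_sigs,
        "cluster_tau": cluster_tau,
        "significant_drugs": per_cluster,
        "significant_union": union,
        "moa_matrix": moa_matrix,
        "moa_enrichment": moa_enrich,
        "reverting_taus": rev_taus,
        "classifier_models": models,
        "best_feature_set": best,
        "holdout_auc": float(auc),
        "meta": meta_result,
    }
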