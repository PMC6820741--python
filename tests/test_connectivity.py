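import numpy as np
import pandas as pd
import pytest

from lupuscmap import connectivity, synthetic
from lupuscmap.connectivity import (
    ConnectivityMatrix,
    absolute_rank_sum_select,
    normalize_and_tau,
    score_library,
    significant_drugs,
    weighted_ks_es,
    wtcs,
)
from lupuscmap.core_io import GeneSignature, RankedProfile
from lupuscmap.errors import ValidationError


def naive_ks_es(gene_set, profile, weight_exp=1.0):
    """O(N*|S|) prefix-scan oracle for the weighted-KS enrichment score."""
    hits = set(gene_set) & set(profile.genes)
    n = len(profile.genes)
    weights = {}
    for g, s in zip(profile.genes, profile.stats):
        if g in hits:
            weights[g] = 1.0 if weight_exp == 0 else abs(s) ** weight_exp
    total = sum(weights.values())
    if total == 0:
        weights = {g: 1.0 for g in hits}
        total = float(len(hits))
    miss_pen = 1.0 / (n - len(hits))
    best, run = 0.0, 0.0
    for g in profile.genes:
        run += weights[g] / total if g in hits else -miss_pen
        if abs(run) > abs(best):
            best = run
    return best


class TestWeightedKS:
    def test_single_gene_at_top(self, profile_factory):
        prof = profile_factory([f"g{i}" for i in range(10)])
        assert weighted_ks_es(["g0"], prof, weight_exp=0) == pytest.approx(1.0)

    def test_single_gene_at_bottom_matches_oracle(self, profile_factory):
        prof = profile_factory([f"g{i}" for i in range(10)])
        es = weighted_ks_es(["g9"], prof, weight_exp=0)
        assert es == pytest.approx(naive_ks_es(["g9"], prof, 0))
        assert es < -0.9  # maximal negative deviation just before the hit

    @pytest.mark.parametrize("weight_exp", [0.0, 1.0, 2.0])
    def test_matches_naive_oracle_random(self, rng, weight_exp):
        genes = [f"g{i}" for i in range(80)]
        for _ in range(25):
            stats = np.sort(rng.normal(size=80))[::-1]
            order = rng.permutation(genes)
            prof = RankedProfile(genes=list(order), stats=stats)
            size = int(rng.integers(1, 20))
            gene_set = list(rng.choice(genes, size=size, replace=False))
            assert weighted_ks_es(gene_set, prof, weight_exp) == pytest.approx(
                naive_ks_es(gene_set, prof, weight_exp), abs=1e-12
            )

    def test_empty_set_rejected(self, profile_factory):
        prof = profile_factory(["g1", "g2"])
        with pytest.raises(ValidationError, match="empty"):
            weighted_ks_es([], prof)

    def test_full_universe_rejected(self, profile_factory):
        prof = profile_factory(["g1", "g2"])
        with pytest.raises(ValidationError, match="universe"):
            weighted_ks_es(["g1", "g2"], prof)

    def test_all_absent_rejected(self, profile_factory):
        prof = profile_factory(["g1", "g2", "g3"])
        with pytest.raises(ValidationError, match="no gene"):
            weighted_ks_es(["x1"], prof)


class TestWTCS:
    def test_sign_mismatch_gives_zero(self, profile_factory):
        # up and down sets both at the top -> both ES positive -> 0
        prof = profile_factory([f"g{i}" for i in range(40)])
        sig = GeneSignature(up=["g0", "g1"], down=["g2", "g3"], origin="q")
        assert wtcs(sig, prof, min_coverage=0.0) == 0.0

    def test_opposing_sets_average(self, profile_factory):
        prof = profile_factory([f"g{i}" for i in range(40)])
        sig = GeneSignature(up=["g0", "g1"], down=["g38", "g39"], origin="q")
        es_up = weighted_ks_es(sig.up, prof)
        es_dn = weighted_ks_es(sig.down, prof)
        assert np.sign(es_up) != np.sign(es_dn)
        assert wtcs(sig, prof) == pytest.approx((es_up - es_dn) / 2)

    def test_self_query_scores_high(self, rng):
        genes = [f"g{i}" for i in range(600)]
        stats = np.sort(rng.normal(size=600))[::-1]
        prof = RankedProfile(genes=list(rng.permutation(genes)), stats=stats)
        sig = GeneSignature(
            up=prof.genes[:150], down=prof.genes[-150:][::-1], origin="self"
        )
        assert wtcs(sig, prof) >= 0.95

    def test_antisymmetry_unweighted(self, rng):
        genes = [f"g{i}" for i in range(100)]
        order = list(rng.permutation(genes))
        stats = np.linspace(2, -2, 100)
        prof = RankedProfile(genes=order, stats=stats)
        rev = RankedProfile(genes=order[::-1], stats=stats)
        sig = GeneSignature(up=genes[:10], down=genes[50:60], origin="q")
        a = wtcs(sig, prof, weight_exp=0, min_coverage=0.0)
        b = wtcs(sig, rev, weight_exp=0, min_coverage=0.0)
        assert abs(a + b) <= 1e-9

    def test_low_coverage_rejected(self, profile_factory):
        prof = profile_factory([f"g{i}" for i in range(40)])
        sig = GeneSignature(up=["g0", "x1", "x2"], down=["g39", "x3", "x4"], origin="q")
        with pytest.raises(ValidationError, match="covers"):
            wtcs(sig, prof)


class TestTau:
    def _matrices(self, ref_row, query_vals, drug="d1"):
        raw = ConnectivityMatrix(
            pd.DataFrame({f"q{i}": [v] for i, v in enumerate(query_vals)}, index=[drug]),
            stage="wtcs",
        )
        ref = ConnectivityMatrix(
            pd.DataFrame(
                np.asarray(ref_row)[None, :],
                index=[drug],
                columns=[f"r{i}" for i in range(len(ref_row))],
            ),
            stage="wtcs",
        )
        return raw, ref

    def test_extreme_percentile_is_100(self):
        ref = list(np.linspace(0.05, 0.5, 20))
        raw, refm = self._matrices(ref, [0.9])
        tau = normalize_and_tau(raw, refm)
        assert tau.values.iloc[0, 0] == pytest.approx(100.0)

    def test_median_percentile_is_50(self):
        # 21 reference scores whose middle value bit-equals the query
        ref = [0.1 + 0.01 * i for i in range(10)] + [0.3] + [0.5 + 0.01 * i for i in range(10)]
        raw, refm = self._matrices(ref, [0.3])
        tau = normalize_and_tau(raw, refm)
        assert tau.values.iloc[0, 0] == pytest.approx(50.0)

    def test_negative_scores_get_negative_tau(self):
        ref = list(np.linspace(0.05, 0.5, 10)) + list(-np.linspace(0.05, 0.5, 10))
        raw, refm = self._matrices(ref, [-0.9])
        tau = normalize_and_tau(raw, refm)
        assert tau.values.iloc[0, 0] == pytest.approx(-100.0)

    def test_joint_rescaling_invariance(self, rng):
        ref = rng.normal(scale=0.3, size=25)
        q = [0.4, -0.2]
        raw, refm = self._matrices(ref, q)
        tau1 = normalize_and_tau(raw, refm).values
        scale = 0.4375  # keeps rescaled WTCS inside [-1, 1]
        raw2, refm2 = self._matrices(ref * scale, [v * scale for v in q])
        tau2 = normalize_and_tau(raw2, refm2).values
        assert np.allclose(tau1.to_numpy(), tau2.to_numpy())

    def test_requires_wtcs_stage(self):
        raw, refm = self._matrices(list(np.linspace(0.1, 0.5, 20)), [0.3])
        bad = ConnectivityMatrix(raw.values * 100, stage="tau")
        with pytest.raises(ValidationError, match="wtcs-stage"):
            normalize_and_tau(bad, refm)

    def test_small_reference_rejected(self):
        raw, refm = self._matrices([0.1, 0.2], [0.3])
        with pytest.raises(ValidationError, match=">= 20"):
            normalize_and_tau(raw, refm)


class TestRankSumSelection:
    def test_consistent_top_drug_retained_with_min_p(self, rng):
        n_drugs, n_pat, n_perm = 50, 10, 500
        scores = rng.uniform(-50, 50, size=(n_drugs, n_pat))
        scores[7] = 99.0  # strongest |tau| for every patient
        cm = ConnectivityMatrix(
            pd.DataFrame(scores, index=[f"d{i}" for i in range(n_drugs)]),
            stage="tau",
        )
        sel = absolute_rank_sum_select(cm, n_perm=n_perm, seed=1)
        assert "d7" in sel.retained
        assert sel.p["d7"] == pytest.approx(1.0 / (n_perm + 1))

    def test_single_patient_rejected(self):
        cm = ConnectivityMatrix(
            pd.DataFrame({"p1": [1.0, 2.0]}, index=["d1", "d2"]), stage="tau"
        )
        with pytest.raises(ValidationError, match=">= 2 patients"):
            absolute_rank_sum_select(cm, n_perm=100)

    def test_too_few_permutations_rejected(self):
        cm = ConnectivityMatrix(
            pd.DataFrame(np.ones((3, 3)), index=list("abc")), stage="tau"
        )
        with pytest.raises(ValidationError, match="n_perm"):
            absolute_rank_sum_select(cm, n_perm=10)


class TestSignificantDrugs:
    def _cm(self, scores):
        return ConnectivityMatrix(
            pd.DataFrame({"cl1": scores}, index=[f"d{i + 1}" for i in range(len(scores))]),
            stage="tau",
        )

    def test_inclusive_absolute_threshold(self):
        per_cluster, mask = significant_drugs(self._cm([-95.0, 30.0, 91.0]))
        assert per_cluster["cl1"] == ["d1", "d3"]

    def test_zero_threshold_keeps_all(self):
        per_cluster, _ = significant_drugs(self._cm([-95.0, 30.0, 91.0]), threshold=0)
        assert per_cluster["cl1"] == ["d1", "d2", "d3"]

    def test_boundary_value_retained(self):
        per_cluster, _ = significant_drugs(self._cm([-90.0, 10.0]))
        assert per_cluster["cl1"] == ["d1"]

    def test_wrong_stage_rejected(self):
        cm = ConnectivityMatrix(
            pd.DataFrame({"cl1": [0.5]}, index=["d1"]), stage="wtcs"
        )
        with pytest.raises(ValidationError, match="tau-stage"):
            significant_drugs(cm)


class TestReversalProperties:
    def test_reverting_profile_scores_strongly_negative(self, rng):
        """A profile built to invert a signature's statistic reverses it."""
        genes = [f"g{i}" for i in range(600)]
        hits = 0
        for rep in range(10):
            stats = np.sort(rng.normal(size=600))[::-1]
            order = list(rng.permutation(genes))
            prof = RankedProfile(genes=order, stats=stats)
            sig = GeneSignature(
                up=prof.genes[:100], down=prof.genes[-100:][::-1], origin="d"
            )
            # negate: reverse ranking, negated statistic stays non-increasing
            anti = RankedProfile(genes=order[::-1], stats=-stats[::-1])
            if wtcs(sig, anti) <= -0.9:
                hits += 1
        assert hits >= 9

    def test_tau_mean_near_zero_on_random_reference(self, rng):
        cfg = synthetic.SimulationConfig(
            n_genes=800, module_size_per_side=50, n_drugs=20,
            n_reverting_per_subgroup=2,
        )
        _clin, truth = synthetic.simulate_clinical(cfg, 5)
        lib = synthetic.simulate_drug_library(cfg, truth, 5)
        refs = synthetic.random_signatures(lib.gene_ids, 25, 50, seed=6)
        queries = synthetic.random_signatures(lib.gene_ids, 10, 50, seed=7)
        raw = score_library(queries, lib)
        ref = score_library(refs, lib)
        tau = normalize_and_tau(raw, ref)
        arr = tau.values.to_numpy()
        assert np.all(np.abs(arr) <= 100 + 1e-9)
        assert abs(arr.mean()) < 15  # random queries should not skew far
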