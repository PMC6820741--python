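import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lupuscmap import signatures
from lupuscmap.core_io import ClinicalTable, ExpressionMatrix
from lupuscmap.errors import ValidationError
from lupuscmap.signatures import (
    DEResult,
    FoldChangeVector,
    cluster_de,
    cluster_signature,
    combine_max_p,
    extract_signature,
    patient_fold_changes,
    select_active_visit,
)


def _clinical(visits):
    """visits: {patient: [sledai...]}"""
    rows = []
    for p, series in visits.items():
        for i, s in enumerate(series):
            rows.append((p, i + 1, s, 50.0, 30.0, 0, "c"))
    return ClinicalTable(
        pd.DataFrame(
            rows,
            columns=[
                "patient_id", "visit_index", "sledai", "neut_pct", "lymph_pct",
                "nephritis", "cohort_id",
            ],
        )
    )


class TestActiveVisit:
    def test_argmax_visit_selected(self):
        sel, excl = select_active_visit(_clinical({"p": [4, 8, 6]}))
        assert sel == {"p": 2}
        assert excl == []

    def test_threshold_is_strict(self):
        sel, excl = select_active_visit(_clinical({"p": [5, 5, 5]}))
        assert sel == {}
        assert excl == ["p"]

    def test_tie_takes_earliest_qualifying_visit(self):
        # exhaustive over 2-visit tie arrangements
        for series, expected in [((8, 8), 1), ((8, 6), 1), ((6, 8), 2)]:
            sel, _ = select_active_visit(_clinical({"p": list(series)}))
            assert sel["p"] == expected, series

    def test_empty_table_rejected(self, small_clinical):
        empty = ClinicalTable(small_clinical.data.iloc[0:0])
        with pytest.raises(ValidationError, match="empty"):
            select_active_visit(empty)


class TestFoldChanges:
    def test_case_equal_to_control_mean_is_zero(self):
        values = pd.DataFrame(
            {"case": [2.0, 3.0], "c1": [1.0, 2.0], "c2": [3.0, 4.0]},
            index=["g1", "g2"],
        )
        em = ExpressionMatrix(
            values=values,
            sample_role={"case": "case", "c1": "control", "c2": "control"},
        )
        (fc,) = patient_fold_changes(em)
        assert np.allclose(fc.lfc, 0.0)

    def test_arithmetic(self):
        values = pd.DataFrame(
            {"case": [5.0], "c1": [1.0], "c2": [3.0]}, index=["g1"]
        )
        em = ExpressionMatrix(
            values=values,
            sample_role={"case": "case", "c1": "control", "c2": "control"},
        )
        (fc,) = patient_fold_changes(em)
        assert fc.lfc[0] == pytest.approx(3.0)

    def test_control_order_invariance(self, rng):
        genes = [f"g{i}" for i in range(20)]
        data = rng.normal(size=(20, 5))
        cols = ["case", "c1", "c2", "c3", "c4"]
        roles = {"case": "case", **{c: "control" for c in cols[1:]}}
        em1 = ExpressionMatrix(pd.DataFrame(data, index=genes, columns=cols), roles)
        perm = ["case", "c3", "c1", "c4", "c2"]
        em2 = ExpressionMatrix(
            pd.DataFrame(data, index=genes, columns=cols)[perm], roles
        )
        fc1 = patient_fold_changes(em1)[0]
        fc2 = patient_fold_changes(em2)[0]
        assert np.allclose(fc1.lfc, fc2.lfc)

    def test_no_controls_rejected(self):
        em = ExpressionMatrix(
            pd.DataFrame({"case": [1.0]}, index=["g1"]), {"case": "case"}
        )
        with pytest.raises(ValidationError, match="control"):
            patient_fold_changes(em)


class TestExtractSignature:
    def test_top_bottom_selection(self):
        fc = FoldChangeVector(["g1", "g2", "g3"], [2.0, 0.0, -2.0], "p")
        sig = extract_signature(fc, n_per_side=1)
        assert sig.up == ["g1"]
        assert sig.down == ["g3"]

    def test_full_size_disjoint(self, rng):
        genes = [f"g{i:04d}" for i in range(400)]
        fc = FoldChangeVector(genes, rng.permutation(400).astype(float), "p")
        sig = extract_signature(fc, n_per_side=150)
        assert len(sig.up) == len(sig.down) == 150
        assert not set(sig.up) & set(sig.down)

    def test_all_equal_breaks_ties_lexicographically(self):
        genes = ["gb", "ga", "gd", "gc"]
        fc = FoldChangeVector(genes, np.zeros(4), "p")
        runs = [extract_signature(fc, n_per_side=2) for _ in range(3)]
        for sig in runs:
            assert sig.up == ["ga", "gb"]
            assert sig.down == ["gc", "gd"]  # up members excluded, then lex order

    def test_monotone_transform_invariance(self, rng):
        genes = [f"g{i}" for i in range(50)]
        lfc = rng.normal(size=50)
        a = extract_signature(FoldChangeVector(genes, lfc, "p"), n_per_side=10)
        b = extract_signature(
            FoldChangeVector(genes, 3.0 * lfc + 1.0, "p"), n_per_side=10
        )
        assert a.up == b.up and a.down == b.down

    def test_small_universe_rejected(self):
        fc = FoldChangeVector(["g1", "g2"], [1.0, -1.0], "p")
        with pytest.raises(ValidationError, match="universe"):
            extract_signature(fc, n_per_side=1000)


def _two_group_matrix(case_vals, ctrl_vals, n_genes=1):
    cols = {}
    roles = {}
    for i, v in enumerate(case_vals):
        cols[f"ca{i}"] = np.full(n_genes, v) if np.isscalar(v) else v
        roles[f"ca{i}"] = "case"
    for i, v in enumerate(ctrl_vals):
        cols[f"co{i}"] = np.full(n_genes, v) if np.isscalar(v) else v
        roles[f"co{i}"] = "control"
    genes = [f"g{i}" for i in range(n_genes)]
    return ExpressionMatrix(pd.DataFrame(cols, index=genes), roles)


class TestClusterDE:
    def test_equal_means_give_p_near_one(self):
        em = _two_group_matrix([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        res = cluster_de(em)
        assert res.p[0] > 0.99

    def test_strong_separation_small_p(self, rng):
        case = np.array([0.0, 0.001, -0.001])
        ctrl = np.array([1.0, 1.001, 0.999])
        em = _two_group_matrix(list(case), list(ctrl))
        res = cluster_de(em)
        assert res.p[0] < 1e-6
        assert res.effect[0] < 0

    def test_matches_pooled_t_oracle(self, rng):
        n_genes = 30
        x = rng.normal(size=(n_genes, 4))
        y = rng.normal(size=(n_genes, 5))
        cols = {f"ca{i}": x[:, i] for i in range(4)}
        cols.update({f"co{i}": y[:, i] for i in range(5)})
        roles = {f"ca{i}": "case" for i in range(4)}
        roles.update({f"co{i}": "control" for i in range(5)})
        em = ExpressionMatrix(
            pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)]), roles
        )
        res = cluster_de(em)
        t_ref, p_ref = sps.ttest_ind(x, y, axis=1, equal_var=True)
        assert np.allclose(res.t, t_ref, atol=1e-10)
        assert np.allclose(res.p, p_ref, atol=1e-10)

    def test_small_group_rejected(self):
        em = _two_group_matrix([1.0], [2.0, 3.0])
        with pytest.raises(ValidationError, match=">= 2 samples"):
            cluster_de(em)

    def test_sign_consistency_invariant(self, rng):
        em = _two_group_matrix(
            [rng.normal(size=10) for _ in range(3)],
            [rng.normal(size=10) for _ in range(3)],
            n_genes=10,
        )
        res = cluster_de(em)
        nz = res.t != 0
        assert np.all(np.sign(res.t[nz]) == np.sign(res.effect[nz]))


class TestCombineMaxP:
    def _de(self, genes, effect, p):
        return DEResult(genes, np.asarray(effect, float),
                        np.sign(np.asarray(effect, float)), np.asarray(p, float))

    def test_max_rule_and_direction(self):
        a = self._de(["g1"], [1.0], [0.01])
        b = self._de(["g1"], [2.0], [0.04])
        c = combine_max_p(a, b)
        assert c.p_max[0] == pytest.approx(0.04)
        assert c.direction[0] == 1

    def test_discordant_excluded(self):
        a = self._de(["g1"], [2.0], [0.01])
        b = self._de(["g1"], [-2.0], [0.01])
        c = combine_max_p(a, b)
        assert c.direction[0] == 0

    def test_self_combination_is_identity_on_p(self, rng):
        genes = [f"g{i}" for i in range(20)]
        eff = rng.normal(size=20)
        p = rng.uniform(size=20)
        a = self._de(genes, eff, p)
        c = combine_max_p(a, a)
        assert np.allclose(c.p_max, p)

    def test_disjoint_universes_rejected(self):
        a = self._de(["g1"], [1.0], [0.5])
        b = self._de(["g2"], [1.0], [0.5])
        with pytest.raises(ValidationError, match="no genes"):
            combine_max_p(a, b)


class TestClusterSignature:
    def _combined(self, n=400, rng=None):
        rng = rng or np.random.default_rng(3)
        genes = [f"g{i:04d}" for i in range(n)]
        p = rng.uniform(size=n)
        direction = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        eff = rng.uniform(0.5, 3.0, size=n)
        return signatures.CombinedDE(genes, p, direction, eff)

    def test_exact_sizes(self):
        sig = cluster_signature(self._combined(), n_per_side=150)
        assert len(sig.up) == len(sig.down) == 150
        assert not set(sig.up) & set(sig.down)

    def test_equal_p_breaks_by_effect(self):
        c = signatures.CombinedDE(
            ["g1", "g2", "g3"],
            np.array([0.5, 0.5, 0.9]),
            np.array([1.0, 1.0, 1.0]),
            np.array([1.0, 2.0, 3.0]),
        )
        # need down side too
        c2 = signatures.CombinedDE(
            c.gene_ids + ["h1", "h2"],
            np.concatenate([c.p_max, [0.1, 0.2]]),
            np.concatenate([c.direction, [-1.0, -1.0]]),
            np.concatenate([c.mean_abs_effect, [1.0, 1.0]]),
        )
        sig = cluster_signature(c2, n_per_side=2)
        assert sig.up == ["g2", "g1"]  # equal p 0.5: larger effect first

    def test_insufficient_concordant_rejected(self):
        c = signatures.CombinedDE(
            ["g1", "g2"], np.array([0.1, 0.1]), np.array([1.0, 0.0]),
            np.array([1.0, 1.0]),
        )
        with pytest.raises(ValidationError, match="concordant"):
            cluster_signature(c, n_per_side=2)
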