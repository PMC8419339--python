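import numpy as np
import pandas as pd
import pytest

from leukodx import (
    SignatureModel,
    ValidationError,
    differential_test,
    select_signature,
)
from oracles import benjamini_hochberg, welch_p


def _two_group_matrix(rng, n_genes=50, n_per_group=10, planted=None):
    """Null log-normal matrix around 50 FPKM with optional planted group means."""
    samples = [f"A{i}" for i in range(n_per_group)] + [f"B{i}" for i in range(n_per_group)]
    labels = pd.Series(["AML"] * n_per_group + ["B-ALL"] * n_per_group, index=samples)
    log2 = rng.normal(np.log2(50.0), 0.4, size=(n_genes, 2 * n_per_group))
    matrix = pd.DataFrame(
        np.power(2.0, log2),
        index=pd.Index([f"G{i}" for i in range(n_genes)], name="gene"),
        columns=samples,
    )
    for gene, (mean_a, mean_b) in (planted or {}).items():
        vals = np.concatenate(
            [
                np.power(2.0, rng.normal(np.log2(mean_a), 0.2, n_per_group)),
                np.power(2.0, rng.normal(np.log2(mean_b), 0.2, n_per_group)),
            ]
        )
        matrix.loc[gene] = vals
    return matrix, labels


class TestDifferentialTest:
    def test_identical_values_give_fold_one_q_one(self, tiny_labels):
        matrix = pd.DataFrame(
            {s: [7.0, 1.0] for s in tiny_labels.index},
            index=pd.Index(["FLAT", "OTHER"], name="gene"),
        )
        matrix.loc["OTHER"] = [1.0, 2.0, 3.0, 4.0]
        res = differential_test(matrix, tiny_labels)
        assert res.loc["FLAT", "fold_change"] == pytest.approx(1.0)
        assert res.loc["FLAT", "q_value"] == pytest.approx(1.0)

    def test_planted_tenfold_gene_detected(self, rng):
        matrix, labels = _two_group_matrix(rng, planted={"G0": (400.0, 40.0)})
        res = differential_test(matrix, labels)
        assert res.loc["G0", "q_value"] < 0.05
        assert res.loc["G0", "fold_change"] == pytest.approx(10.0, rel=0.35)
        # independent check with a from-scratch Welch test on the same log data
        a = np.log2(matrix.loc["G0", labels == "AML"].to_numpy() + 1.0)
        b = np.log2(matrix.loc["G0", labels == "B-ALL"].to_numpy() + 1.0)
        assert welch_p(list(a), list(b)) < 1e-4

    def test_null_data_yields_no_discoveries(self, rng):
        matrix, labels = _two_group_matrix(rng, n_genes=300)
        shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        res = differential_test(matrix, shuffled)
        assert (res["q_value"] < 0.05).mean() <= 0.01

    def test_small_group_rejected(self, tiny_matrix):
        labels = pd.Series(
            ["AML", "B-ALL", "B-ALL", "B-ALL"], index=tiny_matrix.columns
        )
        with pytest.raises(ValidationError, match="AML"):
            differential_test(tiny_matrix, labels)

    def test_q_values_match_brute_force_bh(self, rng):
        matrix, labels = _two_group_matrix(rng, n_genes=40, n_per_group=5)
        res = differential_test(matrix, labels)
        log = np.log2(matrix.to_numpy() + 1.0)
        a, b = log[:, :5], log[:, 5:]
        p_oracle = [welch_p(list(a[i]), list(b[i])) for i in range(len(matrix))]
        np.testing.assert_allclose(res["p_value"], p_oracle, rtol=1e-10)
        np.testing.assert_allclose(
            res["q_value"], benjamini_hochberg(p_oracle), rtol=1e-10
        )


class TestSelectSignature:
    def _results(self, rows):
        frame = pd.DataFrame(
            rows, columns=["mean_a", "mean_b", "fold_change", "p_value", "q_value"]
        )
        frame.index = pd.Index([f"G{i}" for i in range(len(frame))], name="gene")
        return frame

    def test_filters_applied_jointly(self):
        res = self._results(
            [
                [150.0, 50.0, 3.0, 0.001, 0.01],  # passes all -> AML
                [80.0, 26.0, 3.0, 0.001, 0.01],  # fails 100-FPKM floor
                [150.0, 50.0, 3.0, 0.2, 0.30],  # fails q
                [150.0, 90.0, 1.7, 0.001, 0.01],  # fails fold
                [40.0, 160.0, 0.25, 0.001, 0.01],  # passes all -> B-ALL
            ]
        )
        model = select_signature(res)
        assert model.aml_genes == ["G0"]
        assert model.ball_genes == ["G4"]

    def test_recovers_planted_signature_exactly(self, default_cohort):
        matrix, labels, truth = default_cohort
        res = differential_test(matrix, labels)
        model = select_signature(res)
        assert set(model.aml_genes) == set(truth.aml_genes)
        assert set(model.ball_genes) == set(truth.ball_genes)

    def test_gene_row_permutation_invariance(self, default_cohort, rng):
        matrix, labels, _ = default_cohort
        shuffled = matrix.iloc[rng.permutation(len(matrix))]
        a = select_signature(differential_test(matrix, labels))
        b = select_signature(differential_test(shuffled, labels))
        assert set(a.aml_genes) == set(b.aml_genes)
        assert set(a.ball_genes) == set(b.ball_genes)

    @pytest.mark.parametrize(
        "tighter", [{"fold_min": 3.0}, {"q_max": 0.01}, {"fpkm_min": 150.0}]
    )
    def test_tightening_any_filter_never_adds_genes(self, default_cohort, tighter):
        matrix, labels, _ = default_cohort
        res = differential_test(matrix, labels)
        loose = select_signature(res)
        tight = select_signature(res, **tighter)
        assert set(tight.aml_genes) <= set(loose.aml_genes)
        assert set(tight.ball_genes) <= set(loose.ball_genes)

    def test_empty_results_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            select_signature(self._results([]).iloc[:0])

    def test_no_genes_selected_warns(self):
        res = self._results([[50.0, 50.0, 1.0, 0.9, 0.95]])
        with pytest.warns(UserWarning) as caught:
            model = select_signature(res)
        messages = {str(w.message) for w in caught}
        assert any("no AML" in m for m in messages)
        assert any("no B-ALL" in m for m in messages)
        assert model.aml_genes == [] and model.ball_genes == []


class TestSignatureModel:
    def test_json_round_trip(self, tmp_path):
        model = SignatureModel(
            aml_genes=["MPO"],
            ball_genes=["PAX5"],
            thresholds={"MPO": 40.0, "PAX5": 12.5},
            reference_level=100.0,
        )
        path = tmp_path / "sig.json"
        model.save(path)
        back = SignatureModel.load(path)
        assert back == model

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValidationError, match="CD19"):
            SignatureModel(aml_genes=["CD19"], ball_genes=["CD19"])

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValidationError, match="MPO"):
            SignatureModel(aml_genes=["MPO"], ball_genes=[], thresholds={"MPO": 0.0})
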