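import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from panlandscape.drug_response import (
    correlate_drug_expression,
    drugs_per_gene,
    resampling_null,
)
from panlandscape.io_formats import GeneSampleMatrix


def _matrix(values, index, semantics, samples=None):
    arr = np.asarray(values, dtype=float)
    samples = samples or [f"CL{i}" for i in range(arr.shape[1])]
    return GeneSampleMatrix(pd.DataFrame(arr, index=index, columns=samples), semantics)


@pytest.fixture
def null_associations():
    rng = np.random.default_rng(11)
    expr = _matrix(rng.normal(size=(4, 30)), ["G1", "G2", "G3", "G4"], "normalized_expression")
    auc = _matrix(rng.normal(size=(5, 30)), [f"D{i}" for i in range(5)], "drug_auc")
    return correlate_drug_expression(expr, auc)


class TestCorrelateDrugExpression:
    def test_monotone_pair_is_resistance(self):
        expr = _matrix([[1, 2, 3, 4, 5]], ["G"], "normalized_expression")
        auc = _matrix([[10, 20, 30, 40, 50]], ["D"], "drug_auc")
        rec = correlate_drug_expression(expr, auc).iloc[0]
        assert rec["rho"] == pytest.approx(1.0)
        assert rec["direction"] == "resistance"
        assert rec["bonferroni_significant"]

    def test_fisher_z_is_atanh_of_rho(self, null_associations):
        for _, rec in null_associations.iterrows():
            assert np.tanh(rec["z"]) == pytest.approx(rec["rho"], abs=1e-10)

    def test_zero_rho_gives_zero_z(self):
        expr = _matrix([[1, 2, 3, 4]], ["G"], "normalized_expression")
        auc = _matrix([[1, -1, -1, 1]], ["D"], "drug_auc")
        rec = correlate_drug_expression(expr, auc).iloc[0]
        assert rec["rho"] == pytest.approx(0.0)
        assert rec["z"] == pytest.approx(0.0)

    def test_missing_auc_handled_pairwise_complete(self):
        rng = np.random.default_rng(12)
        expr = _matrix(rng.normal(size=(1, 20)), ["G"], "normalized_expression")
        auc_vals = rng.normal(size=(1, 20))
        auc_vals[0, :5] = np.nan
        auc = _matrix(auc_vals, ["D"], "drug_auc")
        rec = correlate_drug_expression(expr, auc).iloc[0]
        assert rec["n"] == 15
        ref = sps.spearmanr(expr.values.iloc[0, 5:], auc.values.iloc[0, 5:])
        assert rec["rho"] == pytest.approx(ref.statistic, abs=1e-12)

    def test_pair_with_too_few_observations_is_missing_row(self):
        expr = _matrix([[1, 2, 3, 4]], ["G"], "normalized_expression")
        auc_vals = np.array([[1.0, np.nan, np.nan, 2.0]])
        auc = _matrix(auc_vals, ["D"], "drug_auc")
        rec = correlate_drug_expression(expr, auc).iloc[0]
        assert np.isnan(rec["rho"])
        assert not rec["bonferroni_significant"]

    def test_pearson_method_flag(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=25)
        expr = _matrix([x], ["G"], "normalized_expression")
        auc = _matrix([2 * x + rng.normal(0, 0.4, 25)], ["D"], "drug_auc")
        rec = correlate_drug_expression(expr, auc, method="pearson").iloc[0]
        ref = np.corrcoef(expr.values.iloc[0], auc.values.iloc[0])[0, 1]
        assert rec["rho"] == pytest.approx(ref, abs=1e-12)

    def test_too_few_shared_lines_rejected(self):
        expr = _matrix([[1, 2]], ["G"], "normalized_expression", samples=["A", "B"])
        auc = _matrix([[1, 2]], ["D"], "drug_auc", samples=["B", "C"])
        with pytest.raises(ValueError):
            correlate_drug_expression(expr, auc)


class TestResamplingNull:
    def test_identical_rhos_give_empirical_p_one(self):
        assoc = pd.DataFrame(
            {"gene": ["G"] * 4, "drug": list("ABCD"), "rho": [0.3] * 4}
        )
        cmp = resampling_null(assoc, [("G", "A")], n_iterations=100, seed=0)
        assert cmp.empirical_p == pytest.approx(1.0)

    def test_planted_strong_pair_beats_null(self, null_associations):
        assoc = null_associations.copy()
        assoc.loc[
            (assoc["gene"] == "G1") & (assoc["drug"] == "D0"), "rho"
        ] = 0.95
        cmp = resampling_null(assoc, [("G1", "D0")], n_iterations=500, seed=1)
        assert cmp.empirical_p <= 0.05

    def test_same_seed_reproduces_null_stats(self, null_associations):
        a = resampling_null(null_associations, [("G1", "D0")], 200, seed=5)
        b = resampling_null(null_associations, [("G1", "D0")], 200, seed=5)
        assert np.array_equal(a.null_stats, b.null_stats)

    def test_empirical_p_definition(self, null_associations):
        cmp = resampling_null(null_associations, [("G1", "D0")], 150, seed=2)
        expected = (1 + (cmp.null_stats >= cmp.observed_stat).sum()) / 151
        assert cmp.empirical_p == pytest.approx(expected)

    def test_too_few_iterations_rejected(self, null_associations):
        with pytest.raises(ValueError, match="100"):
            resampling_null(null_associations, [("G1", "D0")], 50, seed=0)

    def test_unknown_target_pair_rejected(self, null_associations):
        with pytest.raises(ValueError, match="not in associations"):
            resampling_null(null_associations, [("G9", "D0")], 100, seed=0)

    def test_pool_exhaustion_rejected(self):
        assoc = pd.DataFrame({"gene": ["G", "G"], "drug": ["A", "B"], "rho": [0.1, 0.2]})
        with pytest.raises(ValueError, match="non-target"):
            resampling_null(assoc, [("G", "A"), ("G", "B")], 100, seed=0)


class TestDrugsPerGene:
    def test_counts_and_order_invariance(self, null_associations):
        assoc = null_associations.copy()
        mask = (assoc["gene"] == "G2") & assoc["drug"].isin(["D1", "D3", "D4"])
        assoc.loc[mask, "bonferroni_significant"] = True
        counts = drugs_per_gene(assoc).set_index("gene")
        shuffled = drugs_per_gene(assoc.sample(frac=1, random_state=0)).set_index("gene")
        assert counts.loc["G2", "n_significant_drugs"] == 3
        assert counts.loc["G1", "n_significant_drugs"] == 0
        pd.testing.assert_frame_equal(counts, shuffled)

    def test_drug_list_sorted_by_abs_rho(self, null_associations):
        assoc = null_associations.copy()
        assoc.loc[(assoc["gene"] == "G1"), "bonferroni_significant"] = True
        assoc.loc[(assoc["gene"] == "G1"), "rho"] = [0.2, -0.9, 0.5, -0.1, 0.7]
        row = drugs_per_gene(assoc).set_index("gene").loc["G1"]
        assert row["drugs"].split(",")[0] == "D1"  # |rho| = 0.9 first
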