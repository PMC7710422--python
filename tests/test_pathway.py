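import numpy as np
import pandas as pd
import pytest

from panlandscape.io_formats import GeneSampleMatrix
from panlandscape.pathway_activity import (
    PathwayDefinition,
    normalize_rppa,
    pas_association,
    pas_associations,
    pas_global_summary,
    pathway_score,
)


def _protein(values, components=None, samples=None):
    arr = np.asarray(values, dtype=float)
    components = components or [f"C{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{i}" for i in range(arr.shape[1])]
    return GeneSampleMatrix(
        pd.DataFrame(arr, index=components, columns=samples), "protein_level"
    )


class TestNormalizeRppa:
    def test_row_centered_on_median_and_scaled(self):
        m = _protein([[1.0, 2.0, 3.0]])
        out = normalize_rppa(m).values.iloc[0]
        assert out.median() == 0.0
        assert out.to_numpy() == pytest.approx(np.array([-1.0, 0.0, 1.0]) / 1.0)

    def test_every_output_row_has_median_zero(self):
        rng = np.random.default_rng(3)
        m = _protein(rng.normal(2.0, 5.0, size=(6, 11)))
        out = normalize_rppa(m)
        assert out.values.median(axis=1).to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_constant_component_dropped_with_warning(self):
        m = _protein([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = normalize_rppa(m)
        assert out.genes == ["C1"]

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(4)
        once = normalize_rppa(_protein(rng.normal(size=(4, 9))))
        twice = normalize_rppa(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestPathwayScore:
    def test_single_activating_member_passes_through(self):
        m = _protein([[2.0, -1.0]], components=["A"])
        pw = PathwayDefinition("p", (("A", 1),))
        assert pathway_score(m, pw).to_numpy() == pytest.approx([2.0, -1.0])

    def test_sign_cancellation(self):
        m = _protein([[1.0], [1.0]], components=["A", "B"])
        pw = PathwayDefinition("p", (("A", 1), ("B", -1)))
        assert pathway_score(m, pw).to_numpy() == pytest.approx([0.0])

    def test_hand_two_sample_three_member_mean(self):
        m = _protein([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]], components=list("ABC"))
        pw = PathwayDefinition("p", (("A", 1), ("B", 1), ("C", -1)))
        # sample 0: (1 + 2 - 3)/3 = 0 ; sample 1: (4 + 5 - 6)/3 = 1
        assert pathway_score(m, pw).to_numpy() == pytest.approx([0.0, 1.0])

    def test_antisymmetric_under_flipping_all_signs(self):
        rng = np.random.default_rng(6)
        m = _protein(rng.normal(size=(3, 7)), components=list("ABC"))
        pw = PathwayDefinition("p", (("A", 1), ("B", -1), ("C", 1)))
        flipped = PathwayDefinition("p", (("A", -1), ("B", 1), ("C", -1)))
        assert pathway_score(m, pw).to_numpy() == pytest.approx(
            -pathway_score(m, flipped).to_numpy()
        )

    def test_linear_in_member_levels(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(2, 5))
        b = rng.normal(size=(2, 5))
        pw = PathwayDefinition("p", (("A", 1), ("B", -1)))
        s = lambda arr: pathway_score(_protein(arr, components=["A", "B"]), pw).to_numpy()
        assert s(2 * a + b) == pytest.approx(2 * s(a) + s(b))

    def test_missing_members_error_names_pathway(self):
        m = _protein([[1.0, 2.0]], components=["X"])
        with pytest.raises(ValueError, match="EMTish"):
            pathway_score(m, PathwayDefinition("EMTish", (("A", 1),)))


class TestPasAssociation:
    def test_constant_pas_gives_p_one_verdict_none(self):
        expr = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=list("ABCDEF"))
        pas = pd.Series([0.5] * 6, index=list("ABCDEF"))
        rec = pas_association(expr, pas, "G", "EMT", "BRCA")
        assert rec["p_value"] == 1.0
        assert rec["verdict"] == "none"

    def test_too_few_samples_rejected(self):
        expr = pd.Series([1.0, 2, 3, 4, 5], index=list("ABCDE"))
        pas = pd.Series([0.1] * 5, index=list("ABCDE"))
        with pytest.raises(ValueError, match=">= 6"):
            pas_association(expr, pas, "G", "EMT", "BRCA")

    def test_strong_shift_called_activation(self):
        samples = [f"S{i}" for i in range(20)]
        expr = pd.Series(np.arange(20, dtype=float), index=samples)
        rng = np.random.default_rng(8)
        pas = pd.Series(
            np.where(np.arange(20) >= 10, 2.0, 0.0) + rng.normal(0, 0.3, 20),
            index=samples,
        )
        rec = pas_association(expr, pas, "G", "EMT", "BRCA")
        assert rec["verdict"] == "activation"
        assert rec["mean_pas_high"] > rec["mean_pas_low"]


class TestPasGlobalSummary:
    def _assoc(self, verdicts):
        return pd.DataFrame(
            {
                "gene": "G",
                "pathway": "EMT",
                "cancer_type": [f"C{i}" for i in range(len(verdicts))],
                "mean_pas_high": 1.0,
                "mean_pas_low": 0.0,
                "p_value": 0.01,
                "fdr": 0.01,
                "verdict": verdicts,
            }
        )

    def test_percentages_over_tested_cancers(self):
        summary = pas_global_summary(self._assoc(["activation"] * 3 + ["none"] * 7))
        assert summary.iloc[0]["pct_activated"] == pytest.approx(30.0)

    def test_five_cancer_filter_boundary_inclusive(self):
        kept = pas_global_summary(self._assoc(["activation"] * 5 + ["none"] * 5))
        assert kept.iloc[0]["heatmap_kept"]
        dropped = pas_global_summary(self._assoc(["activation"] * 4 + ["none"] * 6))
        assert not dropped.iloc[0]["heatmap_kept"]

    def test_empty_associations_rejected(self):
        with pytest.raises(ValueError):
            pas_global_summary(pd.DataFrame())


def test_batch_associations_match_single_path():
    rng = np.random.default_rng(9)
    samples = [f"S{i}" for i in range(16)]
    expr = GeneSampleMatrix(
        pd.DataFrame(rng.normal(size=(2, 16)), index=["G1", "G2"], columns=samples),
        "normalized_expression",
    )
    rppa = GeneSampleMatrix(
        pd.DataFrame(rng.normal(size=(3, 16)), index=list("ABC"), columns=samples),
        "protein_level",
    )
    pws = [PathwayDefinition("p1", (("A", 1), ("B", -1))),
           PathwayDefinition("p2", (("C", 1),))]
    batch = pas_associations(expr, rppa, pws, "BRCA")
    from panlandscape.pathway_activity import normalize_rppa, pathway_score

    normalized = normalize_rppa(rppa)
    for _, row in batch.iterrows():
        pas = pathway_score(normalized, next(p for p in pws if p.name == row["pathway"]))
        single = pas_association(
            expr.values.loc[row["gene"]], pas, row["gene"], row["pathway"], "BRCA"
        )
        assert row["p_value"] == pytest.approx(single["p_value"], abs=1e-12)
        assert row["mean_pas_high"] == pytest.approx(single["mean_pas_high"], abs=1e-12)
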