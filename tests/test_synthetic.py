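import json

import numpy as np
import pandas as pd
import pytest

import panlandscape as pl
from panlandscape.synthetic import CohortConfig, SyntheticTruth, load_bundle


def _null_config(**kwargs):
    defaults = dict(
        cancer_types=("BRCA",),
        n_background_genes=10,
        n_tumor=10,
        n_normal=5,
        n_cell_lines=20,
        n_drugs=4,
        seed=3,
        truth=SyntheticTruth(),
    )
    defaults.update(kwargs)
    return CohortConfig(**defaults)


class TestConfigValidation:
    def test_minimum_group_sizes(self):
        with pytest.raises(ValueError, match="n_tumor"):
            _null_config(n_tumor=2)

    def test_event_rates_must_sum_to_one(self):
        with pytest.raises(ValueError, match="cnv_event_rates"):
            _null_config(cnv_event_rates=(0.5, 0.5, 0.5, 0.0, 0.0))

    def test_planted_gene_must_exist(self):
        with pytest.raises(ValueError, match="NOPE"):
            _null_config(truth=SyntheticTruth(cnv_dosage_slope={"NOPE": 0.5}))

    def test_drug_rho_bounds(self):
        with pytest.raises(ValueError, match="drug_rho"):
            SyntheticTruth(drug_rho={("HIF1A", "D"): 1.0})

    def test_bad_hazard_direction(self):
        with pytest.raises(ValueError, match="hazard_direction"):
            SyntheticTruth(hazard_direction={("HIF1A", "BRCA"): "sideways"})


class TestDeterminism:
    def test_same_seed_identical_files(self, tmp_path):
        for d in ("a", "b"):
            pl.generate_cohort(_null_config(truth=None)).save(tmp_path / d)
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_different_seed_differs(self):
        a = pl.generate_cohort(_null_config(seed=1))
        b = pl.generate_cohort(_null_config(seed=2))
        assert not a.counts["BRCA"].values.equals(b.counts["BRCA"].values)


class TestPlantedStructure:
    def test_null_cohort_has_centered_fold_changes(self):
        cfg = _null_config(n_background_genes=200, n_tumor=30, n_normal=30)
        bundle = pl.generate_cohort(cfg)
        counts = bundle.counts["BRCA"].values
        tum = counts.iloc[:, :30].mean(axis=1)
        nor = counts.iloc[:, 30:].mean(axis=1)
        lfc = np.log2((tum + 0.5) / (nor + 0.5))
        assert abs(np.median(lfc)) < 0.1

    def test_copula_reproduces_planted_drug_correlation(self):
        cfg = _null_config(
            n_cell_lines=500,
            truth=SyntheticTruth(drug_rho={("HIF1A", "Docetaxel"): 0.9}),
        )
        bundle = pl.generate_cohort(cfg)
        x = bundle.cellline_expression.values.loc["HIF1A"]
        y = bundle.drug_auc.values.loc["Docetaxel"]
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.9, abs=0.1)

    def test_planted_beta_shift_moves_tumor_mean(self):
        cfg = _null_config(
            n_tumor=200, n_normal=200,
            truth=SyntheticTruth(meth_effect={("HIF1A", "BRCA"): 0.2}),
        )
        bundle = pl.generate_cohort(cfg)
        beta = bundle.beta["BRCA"].values.loc["HIF1A"]
        delta = beta.iloc[:200].mean() - beta.iloc[200:].mean()
        assert delta == pytest.approx(0.2, abs=0.06)

    def test_mutation_frequency_matches_planted_rate(self):
        cfg = _null_config(
            n_tumor=300, truth=SyntheticTruth(mut_freq={("HIF1A", "BRCA"): 0.3})
        )
        bundle = pl.generate_cohort(cfg)
        rec = bundle.maf["BRCA"].records
        nonsilent = rec[rec["Variant_Classification"] != "Silent"]
        freq = nonsilent["Tumor_Sample_Barcode"].nunique() / 300
        assert freq == pytest.approx(0.3, abs=0.07)

    def test_survival_censoring_near_configured_fraction(self):
        cfg = _null_config(n_tumor=400)
        bundle = pl.generate_cohort(cfg)
        surv = bundle.survival["BRCA"]
        assert 1 - surv["event"].mean() == pytest.approx(0.30, abs=0.08)

    def test_matrix_semantics_hold_per_layer(self, mini_bundle):
        assert mini_bundle.counts["BRCA"].semantics == "raw_count"
        assert mini_bundle.beta["BRCA"].values.to_numpy().max() <= 1.0
        cnv_vals = mini_bundle.cnv["BRCA"].values.to_numpy()
        assert set(np.unique(cnv_vals)) <= {-2.0, -1.0, 0.0, 1.0, 2.0}


class TestPathwayDefinitions:
    def test_ten_unique_pathways(self):
        pws = pl.emit_pathway_definitions()
        names = [p.name for p in pws]
        assert len(names) == 10
        assert len(set(names)) == 10
        assert {"apoptosis", "cell cycle", "DNA damage response", "EMT",
                "hormone AR", "hormone ER", "PI3K/AKT", "RAS/MAPK", "RTK",
                "TSC/mTOR"} == set(names)

    def test_members_signed_and_inhibitory_present(self):
        pws = pl.emit_pathway_definitions()
        assert all(len(p.members) >= 3 for p in pws)
        assert all(s in (1, -1) for p in pws for _, s in p.members)
        assert any(s == -1 for p in pws for _, s in p.members)


class TestTruthSerialization:
    def test_json_round_trip(self, tmp_path):
        truth = pl.default_truth(("BRCA", "UCEC"), ("Docetaxel", "DRUG02"))
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        assert back.de_log2fc == truth.de_log2fc
        assert back.pas_shift == truth.pas_shift
        assert back.drug_rho == truth.drug_rho
        assert back.hazard_direction == truth.hazard_direction
        json.loads(path.read_text())  # valid JSON on disk


def test_bundle_save_load_round_trip(tmp_path, mini_bundle):
    mini_bundle.save(tmp_path / "cohort")
    back = load_bundle(tmp_path / "cohort", seed=7)
    pd.testing.assert_frame_equal(
        back.counts["BRCA"].values, mini_bundle.counts["BRCA"].values,
        check_names=False,
    )
    assert back.truth.de_log2fc == mini_bundle.truth.de_log2fc
    assert [p.name for p in back.pathways] == [p.name for p in mini_bundle.pathways]
    assert len(back.maf["UCEC"]) == len(mini_bundle.maf["UCEC"])
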