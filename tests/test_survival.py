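import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from _oracles import logrank_bruteforce
from panlandscape.io_formats import GeneSampleMatrix
from panlandscape.survival_landscape import (
    logrank_median_split,
    logrank_statistic,
    survival_associations,
)


def _expr(values, samples):
    return GeneSampleMatrix(
        pd.DataFrame([values], index=["G"], columns=samples), "normalized_expression"
    )


def _surv(samples, times, events):
    return pd.DataFrame({"sample": samples, "time": times, "event": events})


class TestLogrankStatistic:
    def test_hand_worked_six_sample_example(self):
        # all deaths, high group dies late: times 1,2,3 low; 4,5,6 high
        chi2, ome = logrank_statistic(
            np.array([1, 2, 3, 4, 5, 6], dtype=float),
            np.ones(6, dtype=int),
            np.array([False, False, False, True, True, True]),
        )
        ref_chi2, ref_ome = logrank_bruteforce(
            [1, 2, 3, 4, 5, 6], [1] * 6, [False, False, False, True, True, True]
        )
        # O - E for high group: 0-1/2 + 0-3/5 + 0-3/4 + 1-1 + 1-1 + 1-1 = -1.85
        assert ome == pytest.approx(-1.85)
        assert chi2 == pytest.approx(ref_chi2)
        assert ome == pytest.approx(ref_ome)

    def test_matches_bruteforce_on_small_random_datasets(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = rng.integers(4, 9)
            time = rng.integers(1, 6, n).astype(float)
            event = rng.integers(0, 2, n)
            group = rng.integers(0, 2, n).astype(bool)
            if event.sum() == 0 or group.all() or not group.any():
                continue
            chi2, ome = logrank_statistic(time, event, group)
            ref_chi2, ref_ome = logrank_bruteforce(time, event, group)
            assert chi2 == pytest.approx(ref_chi2, abs=1e-12)
            assert ome == pytest.approx(ref_ome, abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(22)
        time = rng.exponential(10, 60)
        event = rng.integers(0, 2, 60)
        group = rng.integers(0, 2, 60).astype(bool)
        chi2, _ = logrank_statistic(time, event, group)
        ref = logrank_test(
            time[group], time[~group], event[group], event[~group]
        )
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_invariant_under_label_swap(self):
        rng = np.random.default_rng(23)
        time = rng.exponential(5, 30)
        event = rng.integers(0, 2, 30)
        group = rng.integers(0, 2, 30).astype(bool)
        chi2_a, ome_a = logrank_statistic(time, event, group)
        chi2_b, ome_b = logrank_statistic(time, event, ~group)
        assert chi2_a == pytest.approx(chi2_b, abs=1e-12)
        assert ome_a == pytest.approx(-ome_b, abs=1e-12)


class TestLogrankMedianSplit:
    def test_high_hazard_high_group_is_unfavorable(self):
        rng = np.random.default_rng(24)
        n = 100
        samples = [f"S{i}" for i in range(n)]
        expr_vals = np.arange(n, dtype=float)
        high = expr_vals > np.median(expr_vals)
        times = np.where(high, rng.exponential(5, n), rng.exponential(20, n))
        rec = logrank_median_split(
            _expr(expr_vals, samples), _surv(samples, times, np.ones(n, int)), "G"
        )
        assert rec["verdict"] == "unfavorable"
        assert rec["o_minus_e_high"] > 0

    def test_all_censored_warns_and_is_ns(self):
        samples = [f"S{i}" for i in range(12)]
        with pytest.warns(UserWarning, match="censored"):
            rec = logrank_median_split(
                _expr(np.arange(12.0), samples),
                _surv(samples, np.arange(1.0, 13.0), np.zeros(12, int)),
                "G",
            )
        assert rec["verdict"] == "ns"

    def test_too_few_samples_rejected(self):
        samples = [f"S{i}" for i in range(5)]
        with pytest.raises(ValueError, match=">= 10"):
            logrank_median_split(
                _expr(np.arange(5.0), samples),
                _surv(samples, np.arange(1.0, 6.0), np.ones(5, int)),
                "G",
            )

    def test_invalid_survival_table_rejected(self):
        samples = [f"S{i}" for i in range(12)]
        bad_event = _surv(samples, np.ones(12), np.full(12, 2))
        with pytest.raises(ValueError, match="binary"):
            logrank_median_split(_expr(np.arange(12.0), samples), bad_event, "G")
        bad_time = _surv(samples, np.full(12, -1.0), np.ones(12, int))
        with pytest.raises(ValueError, match="non-negative"):
            logrank_median_split(_expr(np.arange(12.0), samples), bad_time, "G")

    def test_null_rejection_rate_controlled(self):
        rng = np.random.default_rng(25)
        rejections = 0
        for _ in range(60):
            n = 40
            samples = [f"S{i}" for i in range(n)]
            rec = logrank_median_split(
                _expr(rng.normal(size=n), samples),
                _surv(samples, rng.exponential(10, n), rng.integers(0, 2, n)),
                "G",
            )
            rejections += rec["verdict"] != "ns"
        assert rejections / 60 <= 0.15


def test_batch_fdr_adjustment_flag():
    rng = np.random.default_rng(26)
    n = 60
    samples = [f"S{i}" for i in range(n)]
    expr = GeneSampleMatrix(
        pd.DataFrame(rng.normal(size=(5, n)), index=[f"G{i}" for i in range(5)],
                     columns=samples),
        "normalized_expression",
    )
    surv = _surv(samples, rng.exponential(10, n), np.ones(n, int))
    plain = survival_associations(expr, surv)
    adjusted = survival_associations(expr, surv, adjust_fdr=True)
    assert "fdr" in adjusted.columns
    assert len(plain) == len(adjusted) == 5
    assert (adjusted["fdr"].to_numpy() >= plain["p_value"].to_numpy() - 1e-12).all()
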