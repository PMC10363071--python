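"""Bland-Altman bias analysis, ANCOVA comparison, bootstrap, rank tests."""

import numpy as np
import pandas as pd
import pytest

from synthce.biasstats import (AncovaComparison, BlandAltman, PairedMeans,
                               ancova_compare, bland_altman, bonferroni,
                               bootstrap_ci, omnibus_and_pairwise)


def records_from(pred, truth, method="m"):
    return [PairedMeans.from_values(f"s{i}", p, t, method=method)
            for i, (p, t) in enumerate(zip(pred, truth))]


class TestBlandAltman:
    def test_constant_offset_recovered_exactly(self):
        truth = np.array([100.0, 200.0, 300.0, 400.0])
        res = bland_altman(records_from(truth + 10.0, truth))
        assert res.mean_bias == pytest.approx(10.0)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.loa_half_width == pytest.approx(0.0, abs=1e-9)
        assert res.classification == "constant"

    def test_doubling_gives_two_thirds_slope_exactly(self):
        truth = np.array([100.0, 150.0, 250.0, 400.0])
        res = bland_altman(records_from(2.0 * truth, truth))
        assert res.slope == pytest.approx(2.0 / 3.0, rel=1e-12)
        assert res.classification == "proportional"

    def test_swapping_prediction_and_truth_negates_bias(self):
        rng = np.random.default_rng(0)
        truth = rng.uniform(100, 400, 20)
        pred = truth + rng.normal(5, 10, 20)
        a = bland_altman(records_from(pred, truth))
        b = bland_altman(records_from(truth, pred))
        assert a.mean_bias == pytest.approx(-b.mean_bias)

    def test_needs_three_records(self):
        with pytest.raises(ValueError):
            bland_altman(records_from([1.0, 2.0], [1.0, 2.0]))

    def test_zero_covariate_variance_falls_back_to_constant_analysis(self):
        recs = [PairedMeans(f"s{i}", i_bar=100.0, delta_i=10.0 + 0.1 * i)
                for i in range(5)]
        res = bland_altman(recs)
        assert np.isnan(res.slope)
        assert res.classification == "constant"

    def test_summary_renders(self):
        truth = np.array([100.0, 200.0, 300.0])
        res = bland_altman(records_from(truth + 5, truth))
        assert "mean bias" in res.summary()
        assert "[+-" in res.cell()

    def test_nonfinite_records_rejected(self):
        with pytest.raises(ValueError):
            PairedMeans("s", i_bar=np.nan, delta_i=0.0)


class TestAncova:
    def _two_methods(self, offset=0.0, n=40, seed=0):
        rng = np.random.default_rng(seed)
        truth = rng.uniform(100, 400, n)
        recs = records_from(truth + rng.normal(0, 5, n), truth, "a")
        recs += records_from(truth + offset + rng.normal(0, 5, n), truth, "b")
        return recs

    def test_coefficients_match_normal_equations_oracle(self):
        recs = self._two_methods(offset=20.0)
        res = ancova_compare(recs)
        df = pd.DataFrame([{"d": r.delta_i, "i": r.i_bar,
                            "b": 1.0 if r.method == "b" else 0.0}
                           for r in recs])
        x = np.column_stack([np.ones(len(df)), df["i"], df["b"]])
        beta, *_ = np.linalg.lstsq(x, df["d"].to_numpy(), rcond=None)
        assert res.params["Intercept"] == pytest.approx(beta[0], abs=1e-8)
        assert res.params["i_bar"] == pytest.approx(beta[1], abs=1e-8)
        assert res.params["C(method)[T.b]"] == pytest.approx(beta[2], abs=1e-8)

    def test_exact_offset_when_delta_shifted_at_fixed_covariate(self):
        """Method b = method a with delta_i shifted +30 HU at identical
        i_bar: the adjusted contrast recovers the shift exactly."""
        rng = np.random.default_rng(1)
        truth = rng.uniform(100, 400, 30)
        pred = truth + rng.normal(0, 8, 30)
        recs_a = records_from(pred, truth, "a")
        recs_b = [PairedMeans(r.subject_id, r.i_bar, r.delta_i + 30.0,
                              method="b") for r in recs_a]
        res = ancova_compare(recs_a + recs_b)
        c = res.pairwise[0]
        assert c.estimate == pytest.approx(30.0, abs=1e-8)
        assert c.p_adj < 1e-6

    def test_requires_two_methods_with_enough_records(self):
        with pytest.raises(ValueError):
            AncovaComparison(records_from([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))

    def test_summary_renders(self):
        res = ancova_compare(self._two_methods())
        assert "pairwise" in res.summary()


class TestBootstrap:
    def test_constant_samples_give_zero_width_interval(self):
        lo, hi = bootstrap_ci(np.full(20, 7.0), n_boot=500, seed=0)
        assert lo == hi == 7.0

    def test_endpoints_ordered(self):
        rng = np.random.default_rng(2)
        lo, hi = bootstrap_ci(rng.normal(size=30), n_boot=1000, seed=1)
        assert lo <= hi

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([])

    def test_interval_contains_true_median_typically(self):
        rng = np.random.default_rng(3)
        lo, hi = bootstrap_ci(rng.normal(0, 1, 200), n_boot=2000, seed=2)
        assert lo < 0 < hi


class TestRankTests:
    def test_identical_groups_give_p_one(self):
        g = [1.0, 1.0, 1.0]
        out = omnibus_and_pairwise([g, g, g])
        assert out["h_p"] == 1.0
        assert all(p == 1.0 for p in out["pairwise_u_p"].values())

    def test_complete_separation_exact_p(self):
        out = omnibus_and_pairwise([[1.0, 2.0, 3.0], [101.0, 102.0, 103.0]])
        assert out["pairwise_u_p"][(0, 1)] == pytest.approx(0.1)

    def test_t_test_routing(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 30), rng.normal(2, 1, 30)
        out = omnibus_and_pairwise([a, b], use_t=True)
        assert out["h_p"] < 0.001

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            omnibus_and_pairwise([[1.0]])


class TestBonferroni:
    def test_multiplies_and_caps(self):
        assert bonferroni([0.01, 0.2, 0.5]) == [
            pytest.approx(0.03), pytest.approx(0.6), 1.0]

    def test_monotone(self):
        raw = [0.001, 0.01, 0.04]
        adj = bonferroni(raw)
        assert adj == sorted(adj)
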