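"""Distribution fitting, one-way sweep, and Monte Carlo analyses."""

import numpy as np
import pandas as pd
import pytest

from ckdcea import Strategy, ceac, fit_distribution, owsa, run_psa, tornado
from ckdcea.params import ParameterRange
from ckdcea.sensitivity import PSAResult, fit_distribution_log_ci


class TestFitDistribution:
    def test_gamma_method_of_moments(self):
        # oracle: sd = (1733-1156)/3.92, shape = m^2/s^2, scale = s^2/m
        spec = fit_distribution(ParameterRange(1445.0, 1156.0, 1733.0, "gamma"))
        assert spec.family == "gamma"
        s = (1733 - 1156) / 3.92
        assert spec.params["shape"] == pytest.approx(1445**2 / s**2, rel=1e-9)
        assert spec.params["scale"] == pytest.approx(s**2 / 1445, rel=1e-9)
        assert spec.params["shape"] == pytest.approx(96.3732, abs=1e-3)
        assert spec.params["scale"] == pytest.approx(14.9938, abs=1e-3)
        assert spec.mean == pytest.approx(1445.0, rel=1e-9)

    def test_beta_symmetric_closed_form(self):
        # base 0.5 with sd 0.1 (range half-width 0.196): alpha = beta = 12
        spec = fit_distribution(ParameterRange(0.5, 0.5 - 0.196, 0.5 + 0.196, "beta"))
        assert spec.family == "beta"
        assert spec.params["alpha"] == pytest.approx(12.0, rel=1e-9)
        assert spec.params["beta"] == pytest.approx(12.0, rel=1e-9)

    def test_degenerate_range_is_point_mass(self):
        spec = fit_distribution(ParameterRange(5.0, 5.0, 5.0, "gamma"))
        assert spec.family == "point"
        rng = np.random.default_rng(0)
        assert spec.sample(rng) == 5.0

    def test_infeasible_beta_falls_back_to_uniform(self):
        # variance (high-low)/3.92 squared exceeds m(1-m) for tiny means
        pr = ParameterRange(0.01, 0.0001, 0.9, "beta")
        spec = fit_distribution(pr)
        assert spec.family == "uniform"
        rng = np.random.default_rng(0)
        draws = spec.sample(rng, size=100)
        assert np.all((draws >= 0.0001) & (draws <= 0.9))

    def test_negative_disutility_fitted_on_magnitude(self):
        spec = fit_distribution(ParameterRange(-0.075, -0.090, -0.060, "beta"))
        assert spec.sign == -1.0
        assert spec.mean == pytest.approx(-0.075, rel=1e-9)
        rng = np.random.default_rng(0)
        assert np.all(spec.sample(rng, size=50) < 0)

    def test_lognormal_log_ci_alternative(self):
        spec = fit_distribution_log_ci(ParameterRange(0.57, 0.46, 0.69, "lognormal"))
        assert spec.params["mu"] == pytest.approx(np.log(0.57))

    @pytest.mark.parametrize(
        "pr",
        [
            ParameterRange(0.0095, 0.0069, 0.0126, "beta"),
            ParameterRange(0.884, 0.707, 1.0, "beta"),
            ParameterRange(1445.0, 1156.0, 1733.0, "gamma"),
            ParameterRange(0.46, 0.37, 0.55, "lognormal"),
            ParameterRange(-0.07, -0.084, -0.056, "beta"),
        ],
    )
    def test_sample_mean_converges_to_base(self, pr):
        # mean within 3 Monte-Carlo standard errors at n = 10,000
        spec = fit_distribution(pr)
        rng = np.random.default_rng(123)
        draws = np.asarray(spec.sample(rng, size=10_000))
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - pr.base) < 3 * se + 1e-12

    def test_fitted_mean_within_two_percent_of_base(self, ref_ps):
        for pid, pr in ref_ps.ranges.items():
            spec = fit_distribution(pr)
            if spec.family in ("point", "uniform"):
                continue
            assert abs(spec.mean - pr.base) <= 0.02 * abs(pr.base) + 1e-12, pid


class TestOWSA:
    def test_unconsumed_parameter_has_zero_swing(self, ref_ps):
        # finerenone AE risk plays no role in triple vs SGLT2i
        entry = owsa(ref_ps, "ae.finerenone.hyperkalemia",
                     reference=Strategy.TRIPLE, comparator=Strategy.SGLT2I)
        assert entry.swing == pytest.approx(0.0, abs=1e-9)

    def test_consumed_parameter_moves_nmb(self, ref_ps):
        entry = owsa(ref_ps, "hr_mortality.SGLT2i",
                     reference=Strategy.TRIPLE, comparator=Strategy.SGLT2I)
        assert entry.swing > 1000

    def test_wtp_linearity_oracle(self, ref_ps):
        # with the deltas fixed, NMB is affine in WTP: swing over a WTP
        # range equals dQ x (high - low)
        from ckdcea.cea import run_cea

        _, incs = run_cea(ref_ps)
        inc = incs[0]
        w_lo, w_hi = 100_000.0, 300_000.0
        nmb_lo = inc.incr_qalys * w_lo - inc.incr_cost
        nmb_hi = inc.incr_qalys * w_hi - inc.incr_cost
        assert nmb_hi - nmb_lo == pytest.approx(inc.incr_qalys * (w_hi - w_lo))

    def test_missing_range_raises(self, ref_ps):
        with pytest.raises(KeyError):
            owsa(ref_ps, "cost.state.Mars")

    def test_tornado_sorted_and_brackets_base(self, ref_ps):
        ids = [
            "hr_mortality.SGLT2i",
            "rel_egfr_decline.SGLT2i",
            "cost.drug.SGLT2i",
            "utility.CKD3",
            "ae.finerenone.aki",
        ]
        df = tornado(ref_ps, param_ids=ids)
        assert list(df.swing) == sorted(df.swing, reverse=True)
        base = df.nmb_base.iloc[0]
        # monotone-response parameters bracket the base-case NMB
        consumed = df[df.swing > 1e-6]
        assert (
            (np.minimum(consumed.nmb_low, consumed.nmb_high) <= base + 1e-6)
            & (np.maximum(consumed.nmb_low, consumed.nmb_high) >= base - 1e-6)
        ).all()


class TestPSA:
    def test_degenerate_ranges_reproduce_base_case(self, ref_ps):
        from ckdcea.cea import run_cea

        ps = ref_ps.copy()
        for pr in ps.ranges.values():
            pr.low = pr.high = pr.base
        res = run_psa(ps, n=1, seed=0)
        _, incs = run_cea(ref_ps)
        for inc in incs:
            df = res.draws[(inc.reference, inc.comparator)]
            assert df.nmb.iloc[0] == pytest.approx(inc.nmb, rel=1e-9)

    def test_seed_reproducibility(self, ref_ps):
        a = run_psa(ref_ps, n=8, seed=42)
        b = run_psa(ref_ps, n=8, seed=42)
        for comp in a.comparisons:
            pd.testing.assert_frame_equal(a.draws[comp], b.draws[comp])

    def test_different_seeds_differ(self, ref_ps):
        a = run_psa(ref_ps, n=4, seed=1)
        b = run_psa(ref_ps, n=4, seed=2)
        comp = a.comparisons[0]
        assert not a.draws[comp].equals(b.draws[comp])

    def test_draw_count_and_fractions(self, ref_ps):
        res = run_psa(ref_ps, n=20, seed=5)
        for comp in res.comparisons:
            assert len(res.draws[comp]) == 20
            assert 0.0 <= res.dominant_fraction(comp) <= 1.0
            assert 0.0 <= res.ce_fraction(comp) <= 1.0

    def test_n_below_one_rejected(self, ref_ps):
        with pytest.raises(ValueError):
            run_psa(ref_ps, n=0, seed=0)


class TestCEAC:
    @staticmethod
    def _hand_psa():
        comp = (Strategy.TRIPLE, Strategy.SGLT2I)
        df = pd.DataFrame(
            {
                "incr_cost": [-100.0, 50.0, 200.0, -10.0],
                "incr_qalys": [0.1, 0.01, -0.05, 0.0],
                "nmb": [0.0] * 4,
            }
        )
        return PSAResult(seed=0, n_iterations=4, wtp=1000.0,
                         comparisons=[comp], draws={comp: df})

    def test_hand_enumerated_fractions(self):
        psa = self._hand_psa()
        curve = ceac(psa, [0.0, 10_000.0])
        col = curve["triple_vs_SGLT2i"]
        # wtp=0: nmb = -dc > 0 for draws 1 and 4 -> 2/4
        assert col.iloc[0] == pytest.approx(0.5)
        # wtp=10000: nmb per draw = [1100, 50, -700, 10] -> 3/4
        assert col.iloc[1] == pytest.approx(0.75)

    def test_all_dominant_draws_give_probability_one(self):
        comp = (Strategy.TRIPLE, Strategy.SGLT2I)
        df = pd.DataFrame({"incr_cost": [-1.0, -2.0], "incr_qalys": [0.1, 0.2],
                           "nmb": [0.0, 0.0]})
        psa = PSAResult(seed=0, n_iterations=2, wtp=1000.0,
                        comparisons=[comp], draws={comp: df})
        curve = ceac(psa, np.linspace(0, 5e5, 7))
        assert (curve["triple_vs_SGLT2i"] == 1.0).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ceac(self._hand_psa(), [])
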