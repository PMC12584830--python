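"""Cohort engine: conservation, ordering, tunnel and oracle checks."""

import numpy as np
import pytest

from ckdcea import HealthState, Strategy, initialize_cohort, run_model, step_cycle
from ckdcea.adjust import StrategyModel, build_strategy_model
from ckdcea.engine import AE_TALLY_TYPES
from ckdcea.params import BaselineDistribution, TransitionMatrix
from ckdcea.states import (
    DEAD,
    LAYER_NO_CV,
    LAYER_POST_CV,
    N_ALIVE,
    N_COMPARTMENTS,
    compartment_index,
)


def _share(d: dict[HealthState, float]) -> dict[HealthState, float]:
    share = {s: 0.0 for s in HealthState}
    share.update(d)
    return share


def _toy_model(death=0.0, first_cv=0.0, subsequent=0.0) -> StrategyModel:
    """Identity-matrix strategy model with uniform risks."""
    return StrategyModel(
        strategy=Strategy.SOC,
        matrix=TransitionMatrix(np.eye(N_ALIVE)),
        first_cv=np.full(N_ALIVE, float(first_cv)),
        subsequent_cv=float(subsequent),
        death=np.full(N_ALIVE, float(death)),
        ae={},
    )


class TestInitialization:
    def test_single_state_cohort(self):
        bd = BaselineDistribution(share=_share({HealthState.CKD3: 1.0}))
        trace = initialize_cohort(bd, n_cycles=3)
        occ = trace.occupancy[0]
        assert occ[compartment_index(HealthState.CKD3, LAYER_NO_CV)] == 1.0
        assert occ.sum() == pytest.approx(1.0)
        assert np.count_nonzero(occ) == 1

    def test_shares_copied_to_no_cv_layer(self):
        bd = BaselineDistribution(
            share=_share(
                {HealthState.CKD12: 0.5, HealthState.CKD3: 0.3, HealthState.CKD4: 0.2}
            )
        )
        occ = initialize_cohort(bd, 1).occupancy[0]
        np.testing.assert_allclose(occ[:3], [0.5, 0.3, 0.2])
        assert occ[N_ALIVE:].sum() == 0.0

    def test_cv_history_share_splits_proportionally(self):
        bd = BaselineDistribution(
            share=_share({HealthState.CKD3: 0.6, HealthState.CKD4: 0.4}),
            cv_history_share=0.1,
        )
        occ = initialize_cohort(bd, 1).occupancy[0]
        assert occ[compartment_index(HealthState.CKD3, LAYER_NO_CV)] == pytest.approx(0.54)
        assert occ[compartment_index(HealthState.CKD3, LAYER_POST_CV)] == pytest.approx(0.06)
        assert occ[compartment_index(HealthState.CKD4, LAYER_POST_CV)] == pytest.approx(0.04)

    def test_invalid_shares_rejected(self):
        bd = BaselineDistribution(share=_share({HealthState.CKD3: 0.7}))
        with pytest.raises(ValueError):
            initialize_cohort(bd, 1)


class TestStepCycle:
    def test_no_risks_identity_matrix_is_noop(self):
        occ = np.zeros(N_COMPARTMENTS)
        occ[0] = 0.4
        occ[5] = 0.6
        new, tallies = step_cycle(occ, _toy_model())
        np.testing.assert_array_equal(new, occ)
        assert tallies.new_deaths == 0.0
        assert tallies.new_first_cv == 0.0

    def test_ckd3_cycle_event_arithmetic(self, ref_ps):
        # cohort fully in CKD3, no CV history: deaths 0.0058 and first CV
        # among survivors 0.9942 x 0.0095
        sm = build_strategy_model(ref_ps, Strategy.SOC)
        occ = np.zeros(N_COMPARTMENTS)
        occ[compartment_index(HealthState.CKD3, LAYER_NO_CV)] = 1.0
        _, tallies = step_cycle(occ, sm)
        assert tallies.new_deaths == pytest.approx(0.0058, abs=1e-12)
        assert tallies.new_first_cv == pytest.approx(0.9942 * 0.0095, abs=1e-12)

    def test_repeated_half_death_gives_geometric_decay(self):
        sm = _toy_model(death=0.5)
        occ = np.zeros(N_COMPARTMENTS)
        occ[0] = 1.0
        occ, _ = step_cycle(occ, sm)
        occ, _ = step_cycle(occ, sm)
        assert occ[DEAD] == pytest.approx(0.75, abs=1e-12)

    def test_first_events_move_to_post_cv_layer(self):
        sm = _toy_model(first_cv=0.2)
        occ = np.zeros(N_COMPARTMENTS)
        occ[0] = 1.0
        new, tallies = step_cycle(occ, sm)
        assert new[0] == pytest.approx(0.8)
        assert new[N_ALIVE] == pytest.approx(0.2)
        assert tallies.new_first_cv == pytest.approx(0.2)
        # post-CV layer is one-directional: next step produces no first events
        new2, tallies2 = step_cycle(new, sm)
        assert new2[N_ALIVE] == pytest.approx(0.2 + 0.8 * 0.2)
        assert tallies2.new_first_cv == pytest.approx(0.8 * 0.2)

    def test_subsequent_events_tallied_without_moving_occupancy(self):
        sm = _toy_model(subsequent=0.3)
        occ = np.zeros(N_COMPARTMENTS)
        occ[N_ALIVE + 2] = 1.0  # post-CV CKD4
        new, tallies = step_cycle(occ, sm)
        np.testing.assert_array_equal(new, occ)
        assert tallies.new_subsequent_cv == pytest.approx(0.3)

    def test_unnormalized_occupancy_rejected(self):
        occ = np.zeros(N_COMPARTMENTS)
        occ[0] = 0.9
        with pytest.raises(ValueError, match="sums to"):
            step_cycle(occ, _toy_model())


class TestRunModel:
    def test_horizon_10_years_gives_30_cycles(self, ref_ps):
        trace = run_model(ref_ps, Strategy.SOC)
        assert trace.n_cycles == 30
        assert trace.occupancy.shape == (31, N_COMPARTMENTS)

    @pytest.mark.parametrize("order", ["death_first", "transition_first"])
    @pytest.mark.parametrize("strategy", list(Strategy))
    def test_mass_conserved_every_cycle(self, ref_ps, strategy, order):
        ref_ps.settings.event_order = order
        trace = run_model(ref_ps, strategy)
        np.testing.assert_allclose(
            trace.occupancy.sum(axis=1), 1.0, atol=1e-9
        )
        assert np.all(np.diff(trace.occupancy[:, DEAD]) >= 0)

    def test_unit_ratios_reproduce_soc_trace(self, ref_ps):
        for eff in (
            ref_ps.effects.hr_first_cv,
            ref_ps.effects.hr_mortality,
            ref_ps.effects.rel_egfr_decline,
            ref_ps.effects.hr_renal_composite,
        ):
            eff[Strategy.TRIPLE] = 1.0
        ref_ps.risks.ae[Strategy.TRIPLE] = dict(ref_ps.risks.ae[Strategy.SOC])
        soc = run_model(ref_ps, Strategy.SOC)
        triple = run_model(ref_ps, Strategy.TRIPLE)
        np.testing.assert_allclose(triple.occupancy, soc.occupancy, atol=1e-12)

    def test_two_state_closed_form_oracle(self):
        # alive/dead reduction: with constant death probability q and no
        # movement, Dead(k) = 1 - (1-q)^k exactly
        q = 0.1
        sm = _toy_model(death=q)
        bd = BaselineDistribution(share=_share({HealthState.CKD12: 1.0}))
        trace = initialize_cohort(bd, 20)
        for k in range(1, 21):
            trace.occupancy[k], _ = step_cycle(trace.occupancy[k - 1], sm)
        expected = 1 - (1 - q) ** np.arange(21)
        np.testing.assert_allclose(trace.occupancy[:, DEAD], expected, atol=1e-12)

    def test_lower_mortality_hazard_never_increases_cumulative_deaths(self, ref_ps):
        soc = run_model(ref_ps, Strategy.SOC)
        triple = run_model(ref_ps, Strategy.TRIPLE)
        assert np.all(
            triple.occupancy[:, DEAD] <= soc.occupancy[:, DEAD] + 1e-12
        )

    def test_acute_dialysis_is_one_cycle_tunnel(self, ref_ps):
        # occupancy of the acute dialysis compartment equals that cycle's
        # inflow: no mass may remain a second cycle
        trace = run_model(ref_ps, Strategy.SOC)
        i = HealthState.DIALYSIS_ACUTE.index
        m = ref_ps.matrix.probs
        assert m[i, i] == 0.0
        # inflow to acute dialysis at cycle k comes only from CKD3/4/5 rows
        for k in range(2, 10):
            prev = trace.state_occupancy(k - 1)
            death = build_strategy_model(ref_ps, Strategy.SOC).death
            inflow = float(((prev * (1 - death)) @ m[:, i]))
            assert trace.state_occupancy(k)[i] == pytest.approx(inflow, abs=1e-12)

    def test_invalid_horizon_rejected(self, ref_ps):
        with pytest.raises(ValueError):
            run_model(ref_ps, Strategy.SOC, horizon_years=0.5)

    def test_ae_tallies_scale_with_alive_mass(self, ref_ps):
        trace = run_model(ref_ps, Strategy.FINERENONE)
        alive0 = 1.0
        assert trace.ae_counts["aki"][1] == pytest.approx(alive0 * 0.0040, abs=1e-12)
        assert trace.ae_counts["hyperkalemia"][1] == pytest.approx(0.0016, abs=1e-12)
        for t in AE_TALLY_TYPES:
            assert np.all(trace.ae_counts[t] >= 0)

    def test_trace_export_has_all_columns(self, ref_ps):
        df = run_model(ref_ps, Strategy.SOC).to_frame()
        assert len(df) == 31
        assert "Dead" in df.columns
        assert "new_first_cv" in df.columns
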