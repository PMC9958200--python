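import numpy as np
import pytest

import hillmuscle as hm
from hillmuscle import MuscleParams
from hillmuscle.activation import StimulationProtocol
from hillmuscle.simulate import ACTIVATION_FLOOR


@pytest.fixture(scope="module")
def p():
    return MuscleParams()


class TestPassiveEquilibrium:
    def test_slack_pee_gives_zero_deformation(self, p):
        d, mtu = hm.equilibrium_ce_length(0.98, p)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert mtu == pytest.approx(0.98 * p.L0 + p.L_see)

    def test_balance_at_optimal_mtu_length(self, p):
        d, _ = hm.equilibrium_ce_length(1.23, p)
        assert d > 0
        assert hm.see_force(d, p) == pytest.approx(hm.pee_force(1.23, p), abs=1e-9)

    def test_closed_form_deformation_at_optimum(self, p):
        d, _ = hm.equilibrium_ce_length(1.0, p)
        expected = hm.see_deformation(hm.pee_force(1.0, p), p)
        assert d == pytest.approx(expected, rel=1e-12)

    def test_out_of_domain_length_rejected(self, p):
        with pytest.raises(ValueError):
            hm.equilibrium_ce_length(2.5, p)


class TestProtocolBuilders:
    def test_twitch_is_single_pulse_at_zero(self, p):
        proto = hm.twitch(p)
        assert proto.pulse_times == (0.0,)

    def test_train_pulse_count(self, p):
        assert hm.train(p, 10.0, 1.0).n_pulses == 10

    def test_brief_tetanus_is_six_pulses_spanning_50ms(self, p):
        proto = hm.brief_tetanus(p)
        assert proto.n_pulses == 6
        assert proto.pulse_times[-1] == pytest.approx(0.050)
        assert np.diff(proto.pulse_times) == pytest.approx(0.010)

    def test_invalid_builder_arguments_rejected(self, p):
        with pytest.raises(ValueError):
            hm.train(p, -5.0, 1.0)
        with pytest.raises(ValueError):
            hm.train(p, 10.0, 0.0)


class TestFixedEndSimulation:
    def test_unstimulated_muscle_is_time_invariant(self, p):
        proto = StimulationProtocol((), (), 0.3)
        rec = hm.simulate_fixed_end(p, proto, initial_l_ce=1.23)
        assert np.all(rec.v_ce == 0.0)
        assert rec.l_ce == pytest.approx(1.23, abs=1e-12)
        assert np.all(rec.active_force == 0.0)
        assert np.ptp(rec.total_force) == pytest.approx(0.0, abs=1e-12)

    def test_force_balance_residual(self, twitch_record_123):
        """Total force equals the SEE force at the constraint deformation
        wherever the force-velocity relation is unclamped (the regime in
        which the three-element constraint defines the CE motion)."""
        rec = twitch_record_123
        p = rec.params
        f_see = hm.see_force(np.maximum(rec.see_deformation, 0.0), p)
        denom = p.fgc * rec.activation * hm.force_length(rec.l_ce, p)
        p_rel = (f_see - rec.passive_force) / np.maximum(denom,
                                                         ACTIVATION_FLOOR)
        interior = (denom >= ACTIVATION_FLOOR) & (p_rel > 0) & \
            (p_rel < p.ecc_c)
        assert interior.sum() > 1000  # covers the whole force transient
        resid = np.abs(rec.total_force - f_see)[interior]
        assert resid.max() < 1e-6

    def test_twitch_amplitude_near_design_value(self, control_metrics_123):
        # the control model is calibrated so a twitch is ~0.2 P0
        assert control_metrics_123.peak_force == pytest.approx(0.2, rel=0.15)

    def test_step_size_convergence(self, p, control_metrics_123):
        fine = hm.twitch_metrics(
            hm.simulate_fixed_end(p, hm.twitch(p), 1.23, dt=5e-5))
        rel = abs(fine.peak_force - control_metrics_123.peak_force)
        assert rel / control_metrics_123.peak_force < 1e-3

    def test_max_tetanus_reaches_p0_with_final_length_on_plateau(self, p):
        rec = hm.simulate_fixed_end(
            p, hm.train(p, 200.0, duration=2.0), initial_l_ce=1.23)
        l_final = rec.l_ce[-1]
        assert p.fl_plateau_low <= l_final <= p.fl_plateau_high
        expected_total = p.fgc * 1.0 + hm.pee_force(l_final, p)
        assert rec.total_force.max() == pytest.approx(expected_total, rel=0.02)
        # CE shortening against the SEE during max force development ~23% L0
        assert 1.23 - l_final == pytest.approx(0.23, abs=0.04)

    def test_stiff_see_limit_matches_instant_activation_oracle(self, p):
        """With a near-rigid SEE the CE barely moves; once velocities vanish
        (steady tetanus) the active force equals fgc * Act * FL pointwise."""
        stiff = p.with_k_see(p.k_see * 30.0)
        rec = hm.simulate_fixed_end(
            stiff, hm.train(stiff, 200.0, duration=0.5), initial_l_ce=1.0)
        assert np.ptp(rec.l_ce) < 0.01  # essentially isometric CE
        oracle = (stiff.fgc * rec.activation[-1]
                  * hm.force_length(rec.l_ce[-1], stiff))
        assert rec.active_force[-1] == pytest.approx(oracle, rel=0.01)

    def test_twitch_force_grows_toward_activation_peak_with_stiffness(self, p):
        """Stiffer SEEs reduce internal shortening, so peak twitch force
        increases monotonically toward the activation-trace ceiling."""
        peaks = []
        for mult in (1.0, 3.0, 10.0):
            q = p.with_k_see(p.k_see * mult)
            rec = hm.simulate_fixed_end(q, hm.twitch(q), initial_l_ce=1.0)
            peaks.append(rec.peak_active_force)
        assert np.all(np.diff(peaks) > 0)
        trace = hm.simulate_activator(hm.twitch(p), p)
        ceiling = p.fgc * trace.act.max() * hm.force_length(1.0, p)
        assert peaks[-1] < ceiling

    def test_release_scale_attenuates_twitch(self, p, control_metrics_123):
        weak = hm.twitch_metrics(
            hm.simulate_fixed_end(p, hm.twitch(p), 1.23, release_scale=0.5))
        assert weak.peak_force < 0.5 * control_metrics_123.peak_force

    def test_record_round_trip_to_csv(self, twitch_record_123, tmp_path):
        out = tmp_path / "rec.csv"
        twitch_record_123.to_csv(out)
        assert out.exists() and out.with_suffix(".json").exists()
        import pandas as pd

        df = pd.read_csv(out)
        assert list(df.columns) == [
            "t", "l_ce", "v_ce", "activator", "activation",
            "active_force", "passive_force", "total_force",
        ]
        assert len(df) == len(twitch_record_123.t)
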