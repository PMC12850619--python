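import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from wepcast import AcquisitionProtocol, PhysioParams, discretize_transit, signal_pair, venous_signal
from wepcast.kinetics import (
    BIN_CENTERS,
    N_BINS,
    arterial_inflow,
    relax_piecewise,
    tissue_magnetization,
    venous_arterial_path,
    venous_tissue_path,
)


def random_protocol(rng) -> AcquisitionProtocol:
    n_pulses = rng.integers(0, 4)
    bs = tuple(sorted(rng.uniform(100.0, 6900.0, size=n_pulses)))
    if len(set(bs)) != len(bs):
        bs = ()
    return AcquisitionProtocol(bs_times=bs, bs_efficiency=float(rng.uniform(0.8, 1.0)))


class TestRelaxPiecewise:
    def test_half_recovery_from_saturation(self):
        t1 = 1500.0
        assert relax_piecewise(0.0, 0.0, t1 * math.log(2), t1, 1.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("horizon", [1.0, 500.0, 20000.0])
    def test_equilibrium_is_a_fixed_point(self, horizon):
        assert relax_piecewise(1.0, 0.0, horizon, 1300.0, 1.0) == pytest.approx(1.0)

    def test_single_ideal_pulse_matches_ode_oracle(self):
        t1, T = 1667.0, 3000.0
        got = relax_piecewise(0.3, 0.0, T, t1, 1.0, (T / 2,), 1.0)
        ref = oracles.ode_relax(0.3, 0.0, T, t1, 1.0, (T / 2,), 1.0)
        assert got == pytest.approx(ref, abs=1e-9)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            relax_piecewise(float("nan"), 0.0, 100.0, 1000.0, 1.0)


class TestArterialInflow:
    def test_no_labeling_equals_control(self, protocol):
        phys = PhysioParams(alpha=0.0)
        for tp in (0.0, 1000.0, 3500.0, 7000.0):
            c = arterial_inflow(tp, 1800.0, "control", phys, protocol)
            l = arterial_inflow(tp, 1800.0, "label", phys, protocol)
            assert l == pytest.approx(c, abs=1e-15)

    def test_fresh_bolus_closed_form_without_bs(self, physio_male, no_bs_protocol):
        # spin arriving right at delta_a crossed the plane at t=0
        da = 1901.0
        got = arterial_inflow(da, da, "label", physio_male, no_bs_protocol)
        expected = 1.0 - 2.0 * 0.86 * math.exp(-da / 1667.0)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_bolus_edges_continuous_from_the_control_side(self, physio, protocol):
        # outside [delta_a, tau+delta_a] the spin is unlabeled: values at the
        # edges approached from outside agree with control
        da = 1500.0
        eps = 1e-6
        for edge in (da, protocol.tau + da):
            out = arterial_inflow(min(edge + eps, protocol.t_acq), da, "label", physio, protocol) \
                if edge == protocol.tau + da else arterial_inflow(edge - eps, da, "label", physio, protocol)
            ctrl = arterial_inflow(edge, da, "control", physio, protocol)
            assert out == pytest.approx(ctrl, abs=1e-4)


class TestTissueMagnetization:
    def test_equilibrium_preserved_without_labeling_or_bs(self, no_bs_protocol):
        phys = PhysioParams(alpha=0.0)
        for dv in (500.0, 3300.0, 6000.0):
            assert tissue_magnetization(dv, "control", phys, no_bs_protocol) == pytest.approx(0.9, abs=1e-12)
            assert tissue_magnetization(dv, "label", phys, no_bs_protocol) == pytest.approx(0.9, abs=1e-12)

    def test_zero_flow_reduces_to_pure_t1_recovery_with_inversions(self, protocol):
        phys = PhysioParams(f=1e-30)  # f=0 limit (validator requires > 0)
        dv = 3000.0
        t_exit = protocol.t_acq - dv
        got = tissue_magnetization(dv, "control", phys, protocol)
        ref = relax_piecewise(0.9, 0.0, t_exit, phys.t1_tissue, 0.9,
                              protocol.bs_times, protocol.bs_efficiency)
        assert got == pytest.approx(ref, rel=1e-9)

    def test_transit_beyond_acquisition_returns_equilibrium_sentinel(self, physio, protocol):
        assert tissue_magnetization(7000.0, "label", physio, protocol) == 0.9
        assert tissue_magnetization(8500.0, "control", physio, protocol) == 0.9

    @pytest.mark.parametrize("cond", ["control", "label"])
    @pytest.mark.parametrize("dv", [800.0, 2500.0, 3300.0, 4200.0, 6500.0])
    def test_matches_fine_step_ode_oracle(self, cond, dv, physio, protocol):
        got = tissue_magnetization(dv, cond, physio, protocol)
        ref = oracles.ode_tissue(dv, cond, physio, protocol)
        assert got == pytest.approx(ref, rel=1e-6)


class TestVenousPaths:
    def test_tissue_path_zero_transit_limit(self, physio, protocol):
        # delta_v -> 0: no blood phase, value is tissue magnetization / lam
        dv = 1e-9
        got = venous_tissue_path(dv, "control", physio, protocol)
        ref = tissue_magnetization(dv, "control", physio, protocol) / physio.lam
        assert got == pytest.approx(ref, rel=1e-9)

    def test_paths_at_equilibrium_without_labeling_or_bs(self, no_bs_protocol):
        phys = PhysioParams(alpha=0.0)
        assert venous_tissue_path(3300.0, "label", phys, no_bs_protocol) == pytest.approx(1.0, abs=1e-12)
        assert venous_arterial_path(3300.0, "control", phys, no_bs_protocol) == pytest.approx(1.0, abs=1e-12)

    def test_vessel_only_label_closed_form_without_bs(self, physio_male, no_bs_protocol):
        dv = 3423.0
        total = (1.0 + physio_male.att_ratio) * dv
        got = venous_arterial_path(dv, "label", physio_male, no_bs_protocol)
        expected = 1.0 - 2.0 * 0.86 * math.exp(-total / 1667.0)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_out_of_bolus_label_equals_control(self, physio, no_bs_protocol):
        # delta_a + delta_v > t_acq: the spin crossed before labeling began
        dv = 6000.0
        l = venous_arterial_path(dv, "label", physio, no_bs_protocol)
        c = venous_arterial_path(dv, "control", physio, no_bs_protocol)
        assert l == c == pytest.approx(1.0)

    @pytest.mark.parametrize("cond", ["control", "label"])
    def test_full_paths_match_ode_oracle(self, cond, physio, protocol):
        for dv in (2000.0, 3300.0, 4500.0):
            assert venous_tissue_path(dv, cond, physio, protocol) == pytest.approx(
                oracles.ode_venous_tissue(dv, cond, physio, protocol), rel=1e-6
            )
            assert venous_arterial_path(dv, cond, physio, protocol) == pytest.approx(
                oracles.ode_venous_arterial(dv, cond, physio, protocol), rel=1e-6
            )


class TestTransitDistribution:
    def test_histogram_mass_and_size(self):
        d = discretize_transit(3300.0, 1161.7)
        assert d.weights.size == N_BINS == 300
        assert d.weights.min() >= 0
        assert abs(d.weights.sum() - 1.0) <= 1e-12

    def test_mode_is_the_bin_nearest_the_mean(self):
        d = discretize_transit(3300.0, 1161.7)
        nearest = BIN_CENTERS[np.abs(BIN_CENTERS - 3300.0).argmin()]
        assert d.bin_centers[d.weights.argmax()] == nearest

    def test_mean_close_to_nominal_for_interior_mode(self):
        # truncation to [0, 9000] shifts the mean by only a few ms here;
        # cross-checked against the analytic truncated-normal mean
        from scipy.stats import truncnorm

        mu, sd = 3300.0, 1161.7
        a, b = (0.0 - mu) / sd, (9000.0 - mu) / sd
        analytic = truncnorm.mean(a, b, loc=mu, scale=sd)
        d = discretize_transit(mu, sd)
        assert d.mean == pytest.approx(analytic, abs=2.0)
        assert abs(d.mean - mu) < 20.0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            discretize_transit(3300.0, 0.0)


class TestVenousSignal:
    def test_pure_vessel_mixture_at_zero_extraction(self, physio, protocol):
        d = discretize_transit(3300.0, physio.sigma_vtt)
        vals = np.array(
            [venous_arterial_path(float(dv), "label", physio, protocol) for dv in d.bin_centers]
        )
        got = venous_signal(0.0, 3300.0, "label", physio, protocol)
        assert got == pytest.approx(float(d.weights @ vals), rel=1e-12)

    def test_alpha_zero_conserves_control_label_equality(self, protocol):
        phys = PhysioParams(alpha=0.0)
        for e, dv in [(0.0, 2500.0), (0.5, 3300.0), (0.97, 4100.0)]:
            sp = signal_pair(e, dv, phys, protocol)
            assert sp.diff == pytest.approx(0.0, abs=1e-15)

    def test_collapsed_vascular_bolus_closed_form(self, physio_male, no_bs_protocol):
        # no bs, dispersion collapsed, E=0: diff is the relaxed bolus amplitude
        dv = 3300.0
        total = (1.0 + physio_male.att_ratio) * dv
        sp = signal_pair(0.0, dv, physio_male, no_bs_protocol, sigma=0.0)
        assert sp.diff == pytest.approx(2 * 0.86 * math.exp(-total / 1667.0), abs=1e-12)

    def test_vascular_diff_decreases_with_transit_time(self, physio, no_bs_protocol):
        dvs = np.linspace(2200.0, 4400.0, 12)
        diffs = [signal_pair(0.0, dv, physio, no_bs_protocol, sigma=0.0).diff for dv in dvs]
        assert np.all(np.diff(diffs) < 0)

    def test_dispersion_refinement_oracle(self, physio, protocol):
        # 10x finer transit histogram quantifies the model's own 300-bin
        # quantization error: ~1e-4 relative for means well inside the
        # transit range, up to ~1e-3 when substantial dispersion mass sits
        # on the labeled-bolus edge kink (delta_v ~ 1930 ms here)
        fine = np.linspace(0.0, 9000.0, 3000)
        for e, dvm, tol in [(0.9, 3300.0, 2.5e-4), (0.5, 2400.0, 2e-3)]:
            for cond in ("control", "label"):
                z = (fine - dvm) / physio.sigma_vtt
                w = np.exp(-0.5 * z * z)
                w /= w.sum()
                vals = np.array(
                    [
                        e * venous_tissue_path(float(dv), cond, physio, protocol)
                        + (1 - e) * venous_arterial_path(float(dv), cond, physio, protocol)
                        for dv in fine
                    ]
                )
                coarse = venous_signal(e, dvm, cond, physio, protocol)
                assert coarse == pytest.approx(float(w @ vals), rel=tol)

    def test_invalid_extraction_fraction_rejected(self, physio, protocol):
        with pytest.raises(ValueError):
            venous_signal(1.0, 3300.0, "control", physio, protocol)
        with pytest.raises(ValueError):
            venous_signal(-0.1, 3300.0, "control", physio, protocol)


class TestModelInvariants:
    def test_randomized_oracle_equivalence(self, physio):
        # closed-form piecewise kinetics vs 0.1 ms RK4 over random scenarios
        rng = np.random.default_rng(7)
        for _ in range(8):
            proto = random_protocol(rng)
            e = float(rng.uniform(0.0, 0.999))
            dv = float(rng.uniform(200.0, 8500.0))
            cond = "label" if rng.integers(2) else "control"
            got = venous_signal(e, dv, cond, physio, proto, sigma=0.0)
            ref = oracles.ode_venous_signal(e, dv, cond, physio, proto)
            assert got == pytest.approx(ref, rel=1e-6)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        e=st.floats(0.0, 0.999),
        dv=st.floats(0.0, 8900.0),
        eff=st.floats(0.0, 1.0),
        u=st.floats(100.0, 6900.0),
    )
    def test_magnetization_bounds(self, e, dv, eff, u):
        physio = PhysioParams()
        proto = AcquisitionProtocol(bs_times=(u,), bs_efficiency=eff)
        for cond in ("control", "label"):
            m = venous_signal(e, dv, cond, physio, proto)
            assert -1.0 - 1e-9 <= m <= max(1.0, physio.lam) + 1e-9

    def test_double_inversion_is_identity(self, physio):
        # two ideal pulses separated by a vanishing interval cancel exactly
        base = AcquisitionProtocol(bs_times=(2200.0,))
        doubled = AcquisitionProtocol(bs_times=(2199.9999999, 2200.0))
        for cond in ("control", "label"):
            a = venous_signal(0.9, 3300.0, cond, physio, AcquisitionProtocol(bs_times=()))
            b = venous_signal(0.9, 3300.0, cond, physio, doubled)
            assert b == pytest.approx(a, abs=1e-9)
        # and a double-strength sanity: one pulse does change the signal
        assert venous_signal(0.9, 3300.0, "control", physio, base) != pytest.approx(
            venous_signal(0.9, 3300.0, "control", physio, AcquisitionProtocol(bs_times=())),
            abs=1e-6,
        )
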