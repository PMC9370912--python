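"""Unit tests for the model right-hand sides and ECG compositions."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ecgsim.models as m
from ecgsim import presets

finite = st.floats(min_value=-10, max_value=10, allow_nan=False)


@pytest.fixture(scope="module")
def het():
    return presets.get_preset("heterogeneous", "normal").params


@pytest.fixture(scope="module")
def rd():
    return presets.get_preset("reaction_diffusion", "normal").params


@pytest.fixture(scope="module")
def ring():
    return presets.get_preset("ring", "normal").params


@pytest.fixture(scope="module")
def qp():
    return presets.get_preset("quasi_periodic", "normal").params


# ---------------------------------------------------------------------------
# heterogeneous network
# ---------------------------------------------------------------------------

class TestHeterogeneous:
    def test_origin_is_equilibrium_bitwise(self, het):
        d = m.heterogeneous_deriv(np.zeros(14), het, np.zeros(3))
        assert np.all(d == 0.0)

    def test_dimension_and_finiteness_contracts(self, het):
        with pytest.raises(ValueError):
            m.heterogeneous_deriv(np.zeros(13), het, np.zeros(3))
        bad = np.zeros(14)
        bad[3] = np.nan
        with pytest.raises(ValueError):
            m.heterogeneous_deriv(bad, het, np.zeros(3))

    @pytest.mark.parametrize("Y, C, expected", [
        (-2.0, 9e-5, 0.0),        # step gates negative drive
        (2.0, 9e-5, 1.8e-4),      # QRS coupling coefficient
        (0.0, 9e-5, 0.0),         # H(0) = 0 convention
    ])
    def test_stimulation_current(self, het, Y, C, expected):
        muscle = replace(het.muscles[2], C=C)
        assert m.stimulation_current(muscle, Y) == pytest.approx(
            expected, abs=0.0)

    @given(y1=finite, y3=finite)
    def test_step_gating_property(self, het, y1, y3):
        # currents vanish for negative drive, are C*Y for positive drive
        for j, Y in enumerate((y1, -y1, y3, -y3)):
            current = m.stimulation_current(het.muscles[j], Y)
            if Y > 0:
                assert current == het.muscles[j].C * Y
            else:
                assert current == 0.0

    def test_compose_baseline_only(self, het):
        state = np.zeros(14)
        assert m.compose_ecg_heterogeneous(state, het, "II") == pytest.approx(0.2)

    def test_compose_sign_pattern(self, het):
        params = replace(het, z0=0.0,
                         alphas={"II": (1.0, 1.0, 1.0, 1.0)})
        state = np.zeros(14)
        state[[6, 8, 10, 12]] = 1.0  # z1..z4 = 1
        assert m.compose_ecg_heterogeneous(state, params, "II") == pytest.approx(2.0)

    def test_compose_linearity(self, het):
        params = replace(het, z0=0.0)
        rng = np.random.default_rng(0)
        s1, s2 = rng.normal(size=(2, 14))
        f = lambda s: m.compose_ecg_heterogeneous(s, params, "II")
        assert f(s1 + s2) == pytest.approx(f(s1) + f(s2))
        assert f(2.0 * s1) == pytest.approx(2.0 * f(s1))

    def test_compose_unknown_channel_lists_available(self, het):
        with pytest.raises(KeyError, match="V6"):
            m.compose_ecg_heterogeneous(np.zeros(14), het, "V9")

    def test_coupling_term_uses_delayed_velocity(self, het):
        state = np.zeros(14)
        d = m.heterogeneous_deriv(state, het, np.array([0.0, 0.5, 0.0]))
        # AV node (index 1) velocity equation picks up K * delayed y_SA
        assert d[3] == pytest.approx(het.pacemakers[1].K * 0.5)
        assert d[5] == 0.0


# ---------------------------------------------------------------------------
# reaction-diffusion network
# ---------------------------------------------------------------------------

class TestReactionDiffusion:
    def test_origin_is_equilibrium_bitwise(self, rd):
        assert np.all(m.rd_deriv(np.zeros(4), rd) == 0.0)

    @pytest.mark.parametrize("state, expected", [
        ((1.0, 0.0, 0.0, 0.0), (1.0, 3.0, 0.0, 0.0)),
        ((0.0, 1.0, 0.0, 0.0), (-1.0, -7.0, 0.0, 8.0)),
    ])
    def test_unit_vector_derivatives(self, rd, state, expected):
        # frozen term-by-term arithmetic with H=3, C=1.35, beta=4
        np.testing.assert_allclose(m.rd_deriv(np.array(state), rd),
                                   expected, rtol=0, atol=1e-15)

    def test_compose_sum_of_weights(self, rd):
        assert m.compose_ecg_rd(np.ones(4), rd) == pytest.approx(0.1164)

    def test_compose_zero_and_projection(self, rd):
        assert m.compose_ecg_rd(np.zeros(4), rd) == 0.0
        proj = replace(rd, K1=1.0, K2=0.0, K3=0.0, K4=0.0)
        state = np.array([0.7, -1.2, 3.4, 0.1])
        assert m.compose_ecg_rd(state, proj) == state[0]

    def test_compose_linearity(self, rd):
        rng = np.random.default_rng(1)
        s1, s2 = rng.normal(size=(2, 4))
        assert m.compose_ecg_rd(s1 + s2, rd) == pytest.approx(
            m.compose_ecg_rd(s1, rd) + m.compose_ecg_rd(s2, rd))


# ---------------------------------------------------------------------------
# delay-coupled ring
# ---------------------------------------------------------------------------

class TestRing:
    def test_difference_coupling_vanishes_at_agreement(self, ring):
        state = np.array([0.3, 0.0, 0.2, 0.0, -0.4, 0.0])
        delayed = {c: state[m.RING_COUPLING_SOURCE[i]]
                   for i, c in enumerate(m.RING_COUPLINGS)}
        # supply the *target* position as the delayed source value for the
        # AV-SA edge: the coupling difference must then contribute nothing
        delayed["AV-SA"] = state[2]
        with_k = m.ring_deriv(state, 0.0, ring, delayed)
        no_k = replace(ring, couplings={**ring.couplings,
                                        "AV-SA": m.RingCoupling(k=0.0)})
        without_k = m.ring_deriv(state, 0.0, no_k, delayed)
        np.testing.assert_array_equal(with_k, without_k)

    def test_missing_delayed_value_for_active_coupling(self, ring):
        delayed = {c: 0.0 for c in m.RING_COUPLINGS}
        delayed["AV-SA"] = math.nan  # k = 5 on this edge
        with pytest.raises(ValueError, match="AV-SA"):
            m.ring_deriv(np.zeros(6), 0.0, ring, delayed)

    def test_sinusoidal_drive_adds_rho(self):
        # ventricular-fibrillation drives: at sin(omega t) = 1 the drive
        # contributes exactly rho to each velocity equation
        preset = presets.get_preset("ring", "ventricular_fibrillation")
        params = preset.params
        silent = replace(params, nodes={
            name: replace(node, rho=0.0)
            for name, node in params.nodes.items()})
        omega = params.nodes["SA"].omega
        t = (math.pi / 2.0) / omega  # sin(omega t) = 1
        state = np.array([0.3, 0.1, 0.2, -0.2, -0.4, 0.5])
        delayed = {c: 0.0 for c in m.RING_COUPLINGS}
        diff = (m.ring_deriv(state, t, params, delayed)
                - m.ring_deriv(state, t, silent, delayed))
        expected = np.zeros(6)
        expected[1] = params.nodes["SA"].rho
        expected[3] = params.nodes["AV"].rho
        expected[5] = params.nodes["HP"].rho
        np.testing.assert_allclose(diff, expected, rtol=1e-12, atol=1e-12)

    def test_compose_baseline_times_scale(self, ring):
        assert m.compose_ecg_ring(np.zeros(6), ring) == pytest.approx(0.0012)

    def test_compose_affine_in_each_variable(self, ring):
        rng = np.random.default_rng(2)
        s = rng.normal(size=6)
        f0 = m.compose_ecg_ring(s, ring)
        for i, alpha in [(0, ring.alpha1), (2, ring.alpha3), (4, ring.alpha5)]:
            bumped = s.copy()
            bumped[i] += 1.0
            assert m.compose_ecg_ring(bumped, ring) - f0 == pytest.approx(
                alpha * ring.beta_G)

    def test_beta_g_must_be_nonzero(self, ring):
        with pytest.raises(ValueError, match="beta_G"):
            replace(ring, beta_G=0.0)


# ---------------------------------------------------------------------------
# quasi-periodic Gaussian-kernel model
# ---------------------------------------------------------------------------

class TestQuasiPeriodic:
    def test_pushpull_vanishes_at_kernel_center(self, qp):
        r_kernel = qp.kernels["R"]
        assert m.kernel_pushpull(r_kernel, r_kernel.theta) == 0.0

    @given(dth=st.floats(min_value=-3.1, max_value=3.1, allow_nan=False))
    def test_pushpull_is_odd(self, dth):
        k = m.GaussianKernel(a=2.0, b=0.3, theta=0.0)
        plus = m.kernel_pushpull(k, dth)
        minus = m.kernel_pushpull(k, -dth)
        assert plus == pytest.approx(-minus, abs=1e-15)

    def test_symmetric_kernel_pair_cancels(self):
        # two kernels with equal amplitude/width placed symmetrically about
        # theta contribute push-pull terms that cancel exactly
        theta = 0.4
        sep = 0.7
        k1 = m.GaussianKernel(a=1.5, b=0.2, theta=theta - sep)
        k2 = m.GaussianKernel(a=1.5, b=0.2, theta=theta + sep)
        total = m.kernel_pushpull(k1, theta) + m.kernel_pushpull(k2, theta)
        assert total == pytest.approx(0.0, abs=1e-15)

    @given(delta=st.floats(min_value=-50, max_value=50, allow_nan=False))
    def test_wrap_angle_bounds(self, delta):
        w = float(m.wrap_angle(delta))
        assert -math.pi <= w < math.pi
        # wrapped difference is congruent to the input mod 2 pi
        assert (delta - w) % (2 * math.pi) == pytest.approx(0.0, abs=1e-9) \
            or (delta - w) % (2 * math.pi) == pytest.approx(2 * math.pi, abs=1e-9)

    def test_channel_derivatives_vanish_at_baseline_with_zero_kernels(self, qp):
        silent = replace(qp, kernels={
            name: replace(k, a=0.0) for name, k in qp.kernels.items()})
        t = 0.37
        z0 = float(m.baseline_wander(t, qp))
        state = np.array([1.0, 0.0, z0, z0, z0])
        d = m.qp_deriv(state, t, silent)
        np.testing.assert_allclose(d[2:], 0.0, atol=1e-15)

    @pytest.mark.parametrize("t_factor, expected_factor", [
        (0.0, 0.0),      # sin(0) = 0
        (0.25, 1.0),     # quarter respiratory period -> full amplitude
    ])
    def test_baseline_wander(self, qp, t_factor, expected_factor):
        t = t_factor / qp.fr
        assert m.baseline_wander(t, qp) == pytest.approx(
            qp.A * expected_factor, abs=1e-15)

    def test_baseline_wander_zero_amplitude(self, qp):
        silent = replace(qp, A=0.0)
        t = np.linspace(0, 10, 101)
        np.testing.assert_array_equal(m.baseline_wander(t, silent), 0.0)

    def test_compose_is_symmetric_sum(self):
        assert m.compose_ecg_qp(np.array([0.0, 0.0, 0.0, 0.0, 0.0])) == 0.0
        assert m.compose_ecg_qp(np.array([1.0, 0.0, 0.1, 1.0, 0.2])) == \
            pytest.approx(1.3)
        assert m.compose_ecg_qp(np.array([1.0, 0.0, 0.2, 0.1, 1.0])) == \
            pytest.approx(1.3)

    def test_kernel_width_must_be_positive(self):
        with pytest.raises(ValueError, match="width"):
            m.GaussianKernel(a=1.0, b=0.0, theta=0.0)

    def test_width_scaled_amplitude_transform(self, qp):
        scaled = m.with_width_scaled_amplitudes(qp)
        r = qp.kernels["R"]
        assert scaled.kernels["R"].a == pytest.approx(r.a * r.b ** 2)

    def test_exactly_one_rate_specification(self, qp):
        with pytest.raises(ValueError, match="omega"):
            replace(qp, omega=None)  # neither omega nor tachogram


def test_composition_linearity_all_models(het, rd, ring, qp):
    """All four composition maps are affine: f(s1+s2) - f(0) =
    (f(s1) - f(0)) + (f(s2) - f(0))."""
    rng = np.random.default_rng(7)
    cases = [
        (14, lambda s: m.compose_ecg_heterogeneous(s, het, "II")),
        (4, lambda s: m.compose_ecg_rd(s, rd)),
        (6, lambda s: m.compose_ecg_ring(s, ring)),
        (5, m.compose_ecg_qp),
    ]
    for dim, f in cases:
        s1, s2 = rng.normal(size=(2, dim))
        f0 = f(np.zeros(dim))
        lhs = f(s1 + s2) - f0
        rhs = (f(s1) - f0) + (f(s2) - f0)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)
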