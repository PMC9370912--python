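"""Unit and property tests for the lead algebra and 12-lead assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ecgsim.integrator as itg
import ecgsim.leads as leads
from ecgsim import presets
from ecgsim.models import LEADS

electrode = st.floats(min_value=-4.0, max_value=4.0, allow_nan=False)


def _electrodes(ra, la, ll):
    return leads.ElectrodePotentials(RA=np.atleast_1d(ra),
                                     LA=np.atleast_1d(la),
                                     LL=np.atleast_1d(ll), fs=500.0)


class TestLimbLeads:
    def test_direct_substitution(self):
        lead_i, lead_ii, lead_iii = leads.limb_leads(
            _electrodes(1.0, 0.5, 0.2))
        assert lead_i.values[0] == pytest.approx(-0.5)
        assert lead_ii.values[0] == pytest.approx(-0.8)
        assert lead_iii.values[0] == pytest.approx(-0.3)
        assert lead_ii.values[0] == pytest.approx(
            lead_i.values[0] + lead_iii.values[0])

    def test_common_mode_rejection(self):
        for tr in leads.limb_leads(_electrodes(0.7, 0.7, 0.7)):
            assert tr.values[0] == 0.0

    @given(ra=electrode, la=electrode, ll=electrode, c=electrode)
    def test_offset_invariance(self, ra, la, ll, c):
        base = leads.limb_leads(_electrodes(ra, la, ll))
        shifted = leads.limb_leads(_electrodes(ra + c, la + c, ll + c))
        for tr_a, tr_b in zip(base, shifted):
            assert tr_a.values[0] == pytest.approx(
                tr_b.values[0], abs=8 * np.spacing(max(abs(ra), abs(la),
                                                       abs(ll), abs(c), 1.0)))

    @given(ra=electrode, la=electrode, ll=electrode)
    def test_einthoven_identity_to_ulps(self, ra, la, ll):
        lead_i, lead_ii, lead_iii = leads.limb_leads(_electrodes(ra, la, ll))
        residual = abs(lead_ii.values[0]
                       - (lead_i.values[0] + lead_iii.values[0]))
        scale = max(abs(ra), abs(la), abs(ll), 1e-30)
        assert residual <= 4 * np.spacing(scale)


class TestAugmentedLeads:
    def test_direct_substitution(self):
        avr, avl, avf = leads.augmented_leads(_electrodes(1.0, 0.5, 0.2))
        assert avr.values[0] == pytest.approx(0.65)
        assert avl.values[0] == pytest.approx(-0.1)
        assert avf.values[0] == pytest.approx(-0.55)

    def test_equal_electrodes_give_zero(self):
        for tr in leads.augmented_leads(_electrodes(-0.3, -0.3, -0.3)):
            assert tr.values[0] == 0.0

    @given(ra=electrode, la=electrode, ll=electrode)
    def test_goldberger_identity_to_ulps(self, ra, la, ll):
        avr, avl, avf = leads.augmented_leads(_electrodes(ra, la, ll))
        residual = abs(avr.values[0] + avl.values[0] + avf.values[0])
        scale = max(abs(ra), abs(la), abs(ll), 1e-30)
        assert residual <= 4 * np.spacing(scale)


class TestSolveElectrodePotentials:
    def test_known_solution(self):
        e = leads.solve_electrode_potentials(
            itg.ECGTrace([1.0], 500.0, "I"), itg.ECGTrace([2.0], 500.0, "II"))
        assert e.RA[0] == pytest.approx(-1.0)
        assert e.LA[0] == pytest.approx(0.0)
        assert e.LL[0] == pytest.approx(1.0)
        # III = II - I = LL - LA
        assert e.LL[0] - e.LA[0] == pytest.approx(1.0)

    def test_zero_leads_give_zero_electrodes(self):
        e = leads.solve_electrode_potentials(
            itg.ECGTrace([0.0], 500.0, "I"), itg.ECGTrace([0.0], 500.0, "II"))
        for arr in (e.RA, e.LA, e.LL):
            np.testing.assert_array_equal(arr, 0.0)

    @given(i_val=electrode, ii_val=electrode)
    def test_round_trip_reproduces_leads(self, i_val, ii_val):
        e = leads.solve_electrode_potentials(
            itg.ECGTrace([i_val], 500.0, "I"),
            itg.ECGTrace([ii_val], 500.0, "II"))
        lead_i, lead_ii, _ = leads.limb_leads(e)
        scale = max(abs(i_val), abs(ii_val), 1e-30)
        assert abs(lead_i.values[0] - i_val) <= 4 * np.spacing(scale)
        assert abs(lead_ii.values[0] - ii_val) <= 4 * np.spacing(scale)
        # zero-sum gauge (Wilson terminal at zero)
        assert abs(e.RA[0] + e.LA[0] + e.LL[0]) <= 4 * np.spacing(scale)

    def test_inverse_on_zero_sum_potentials_is_identity(self):
        rng = np.random.default_rng(5)
        ra, la = rng.normal(size=(2, 50))
        ll = -(ra + la)  # zero-sum gauge
        lead_i, lead_ii, _ = leads.limb_leads(_electrodes(ra, la, ll))
        e = leads.solve_electrode_potentials(lead_i, lead_ii)
        np.testing.assert_allclose(e.RA, ra, atol=1e-14)
        np.testing.assert_allclose(e.LA, la, atol=1e-14)
        np.testing.assert_allclose(e.LL, ll, atol=1e-14)

    def test_fs_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sampling"):
            leads.solve_electrode_potentials(
                itg.ECGTrace([1.0], 500.0), itg.ECGTrace([1.0], 250.0))


@pytest.fixture(scope="module")
def profile():
    preset = presets.get_preset("heterogeneous", "normal")
    traj = itg.integrate("heterogeneous", preset.params,
                         itg.IntegrationConfig(duration=12.0))
    return preset, traj, leads.twelve_lead_profile(
        traj, preset.params, fs=500.0, gain=1.0)


class TestTwelveLeadProfile:
    def test_all_channels_present_with_common_base(self, profile):
        _, _, lead_set = profile
        assert set(lead_set.channels) == set(LEADS)
        sizes = {lead_set[name].values.size for name in LEADS}
        assert len(sizes) == 1

    def test_lead_identities_hold(self, profile):
        _, _, lead_set = profile
        scale = max(np.max(np.abs(lead_set[n].values)) for n in LEADS)
        tol = 64 * np.finfo(float).eps * scale
        np.testing.assert_allclose(
            lead_set["II"].values,
            lead_set["I"].values + lead_set["III"].values, atol=tol)
        np.testing.assert_allclose(
            lead_set["aVR"].values + lead_set["aVL"].values
            + lead_set["aVF"].values, 0.0, atol=tol)

    def test_gain_calibrates_lead_ii(self, profile):
        _, _, lead_set = profile
        assert itg.peak_magnitude(lead_set["II"].values) == pytest.approx(1.0)

    def test_equal_precordial_weights_give_identical_traces(self, profile):
        preset, traj, _ = profile
        raw = presets.preset_raw("heterogeneous", "normal")
        for ch in ("V1", "V2", "V3", "V4", "V5", "V6"):
            raw["alphas"][ch] = [0.3, 0.3, 0.5, 0.4]
        params = presets.build_params("heterogeneous", raw)
        lead_set = leads.twelve_lead_profile(traj, params, fs=250.0)
        for ch in ("V2", "V3", "V4", "V5", "V6"):
            np.testing.assert_array_equal(lead_set[ch].values,
                                          lead_set["V1"].values)

    def test_zero_trajectory_with_zero_baseline_gives_zero_channels(self):
        raw = presets.preset_raw("heterogeneous", "normal")
        raw["z0"] = 0.0
        params = presets.build_params("heterogeneous", raw)
        t = np.arange(2001) * 1e-3
        traj = itg.Trajectory(model="heterogeneous", t=t,
                              states=np.zeros((t.size, 14)))
        with pytest.warns(UserWarning, match="flat"):
            lead_set = leads.twelve_lead_profile(traj, params, fs=100.0)
        for name in LEADS:
            np.testing.assert_array_equal(lead_set[name].values, 0.0)

    def test_missing_weight_row_names_channel(self):
        raw = presets.preset_raw("heterogeneous", "normal")
        del raw["alphas"]["V3"]
        params = presets.build_params("heterogeneous", raw)
        t = np.arange(101) * 1e-3
        traj = itg.Trajectory(model="heterogeneous", t=t,
                              states=np.zeros((t.size, 14)))
        with pytest.raises(ValueError, match="V3"):
            leads.twelve_lead_profile(traj, params)

    def test_wrong_model_trajectory_rejected(self):
        params = presets.get_preset("heterogeneous", "normal").params
        traj = itg.Trajectory(model="ring", t=np.arange(10.0),
                              states=np.zeros((10, 6)))
        with pytest.raises(ValueError, match="heterogeneous"):
            leads.twelve_lead_profile(traj, params)
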