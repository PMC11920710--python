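"""Rheology, flow split, pulsatile wall shear synthesis and time averaging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tawssnet as tn
from tawssnet.geometry import VESSEL_CODES, build_centerlines, sample_surface
from tawssnet.morphology import MorphologyParams
from tawssnet.surrogate import (
    BLOOD_CARREAU_YASUDA,
    DomainError,
    FlowState,
    ModulatorConfig,
    ViscosityParams,
    carreau_yasuda_viscosity,
    default_flow_state,
    label_model,
    murray_flow_split,
    tawss,
    two_lobe_waveform,
    wall_shear_series,
)


class TestViscosity:
    def test_zero_shear_returns_mu0(self):
        assert carreau_yasuda_viscosity(0.0) == pytest.approx(0.056, abs=0.0)

    def test_high_shear_approaches_mu_inf(self):
        mu = carreau_yasuda_viscosity(1e6)
        assert mu == pytest.approx(0.0035, rel=1e-3)

    def test_unit_shear_value(self):
        # independent hand evaluation of the closed form:
        # (0.056-0.0035)*(1+(1.902*1)^1.25)^((0.22-1)/1.25)+0.0035
        expected = (0.056 - 0.0035) * (1.0 + 1.902**1.25) ** ((0.22 - 1.0) / 1.25) + 0.0035
        assert expected == pytest.approx(0.0287, abs=5e-5)
        assert carreau_yasuda_viscosity(1.0) == pytest.approx(expected, rel=1e-12)

    def test_bounds_and_monotonicity_on_log_grid(self):
        gd = np.logspace(-3, 6, 200)
        mu = carreau_yasuda_viscosity(gd)
        vp = BLOOD_CARREAU_YASUDA
        assert np.all(mu <= vp.mu_0 + 1e-15) and np.all(mu >= vp.mu_inf - 1e-15)
        assert np.all(np.diff(mu) < 0)

    def test_negative_shear_rejected(self):
        with pytest.raises(DomainError):
            carreau_yasuda_viscosity(-1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(DomainError):
            ViscosityParams(mu_inf=0.06, mu_0=0.056)


class TestFlowSplit:
    def test_symmetric(self):
        assert murray_flow_split(2.0, 2.0) == {"LAD": 0.5, "LCX": 0.5}

    def test_cube_law(self):
        f = murray_flow_split(2.0, 1.0)
        assert f["LAD"] == pytest.approx(8.0 / 9.0, abs=1e-15)
        assert f["LCX"] == pytest.approx(1.0 / 9.0, abs=1e-15)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        d1=st.floats(0.5, 6.0, allow_nan=False),
        d2=st.floats(0.5, 6.0, allow_nan=False),
    )
    def test_fractions_sum_to_one(self, d1, d2):
        f = murray_flow_split(d1, d2)
        assert abs(f["LAD"] + f["LCX"] - 1.0) < 1e-12

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(DomainError):
            murray_flow_split(0.0, 2.0)


class TestWaveformAndFlow:
    def test_cycle_mean_is_one(self):
        w = two_lobe_waveform()
        u = np.linspace(0, 1, 200001)
        assert np.trapezoid(w(u), u) == pytest.approx(1.0, abs=1e-6)

    def test_nonnegative(self):
        w = two_lobe_waveform()
        assert np.all(w(np.linspace(0, 1, 5000)) >= 0)

    def test_flow_conservation(self):
        p = MorphologyParams(3.0, 2.0, 2.5, 150.0, 60.0, "t")
        flow = default_flow_state(p)
        t = np.linspace(0, flow.period, 97)
        total = flow.q_of("LAD", t) + flow.q_of("LCX", t)
        assert np.allclose(total, flow.q_of("LM", t), rtol=1e-12, atol=1e-9)

    def test_bad_fractions_rejected(self):
        with pytest.raises(DomainError):
            FlowState(q_mean_lm=100.0, q_fractions={"LAD": 0.6, "LCX": 0.6})


@pytest.fixture(scope="module")
def setup():
    p = MorphologyParams(3.0, 2.5, 2.5, 160.0, 60.0, "t")
    cls = build_centerlines(p)
    cloud = sample_surface(cls, p, 32, 32)
    return p, cls, cloud


class TestWallShear:

    def test_steady_poiseuille_closed_form(self, setup):
        """Far from the junction with modulators off, the surrogate equals the
        Poiseuille wall shear evaluated by hand."""
        p, cls, cloud = setup
        flow = default_flow_state(p)
        flow.waveform = lambda u: np.ones_like(np.asarray(u, dtype=float))
        t = np.linspace(0, flow.period, 16)
        wss, _ = wall_shear_series(
            cloud, p, flow, mod_cfg=ModulatorConfig(enabled=False), t_grid=t, centerlines=cls
        )
        # an LM point on the first station: pure tube
        i = 0
        q = flow.q_mean_lm
        gd = 32.0 * q / (math.pi * p.d_lm**3)
        tau = carreau_yasuda_viscosity(gd) * gd
        assert wss[i] == pytest.approx(tau, rel=1e-9)

    def test_shear_rate_cubic_in_diameter(self):
        q = 1000.0
        gd = lambda d: 32.0 * q / (math.pi * d**3)
        assert gd(1.5) / gd(3.0) == pytest.approx(8.0, rel=1e-12)

    def test_front_back_asymmetry_ratio(self, morphs):
        cloud, fld = label_model(morphs[0], grid_rows=64, grid_cols=64)
        lm = (cloud.vessel_label == VESSEL_CODES["LM"]) & (cloud.station_index < 8)
        ang, v = cloud.circ_angle[lm], fld.values[lm]
        ratio = v[np.cos(ang) > 0].mean() / v[np.cos(ang) < 0].mean()
        assert ratio == pytest.approx(1.25, abs=0.02)

    def test_newtonian_linearity_limit(self, setup):
        """With constant viscosity and modulators off, TAWSS equals the stress
        at the (grid) cycle-mean flow for any waveform: WSS is linear in Q."""
        p, cls, cloud = setup
        vp = ViscosityParams(mu_inf=0.0035, mu_0=0.0035 + 1e-12, lambda_cy=1.902, m=0.22, a=1.25)
        flow = default_flow_state(p)
        t = np.linspace(0, flow.period, 64)
        wss, _ = wall_shear_series(
            cloud, p, flow, vp=vp, mod_cfg=ModulatorConfig(enabled=False), t_grid=t, centerlines=cls
        )
        fld = tawss(wss, t)
        q_mean_grid = np.trapezoid(flow.q_of("LM", t), t) / flow.period
        gd = 32.0 * q_mean_grid / (math.pi * p.d_lm**3)
        tau = 0.0035 * gd
        lm_first_station = 0
        assert fld.values[lm_first_station] == pytest.approx(tau, rel=1e-6)


class TestTawss:
    def test_constant_series(self):
        t = np.linspace(0, 0.8, 33)
        wss = np.full((5, 33), 7.5)
        assert np.allclose(tawss(wss, t).values, 7.5)

    def test_linear_series_exact_for_trapezoid(self):
        t = np.linspace(0, 1.0, 21)
        wss = (2.0 * t / 1.0)[None, :]
        assert tawss(wss, t).values[0] == pytest.approx(1.0, abs=1e-9)

    def test_coarse_grid_matches_fine_oracle(self):
        """64-point pipeline quadrature against a 1024-point oracle."""
        rng = np.random.default_rng(0)
        t_fine = np.linspace(0, 0.8, 1025)
        t_coarse = np.linspace(0, 0.8, 65)
        # random smooth periodic series from a few Fourier modes
        coef = rng.normal(size=(4, 3))
        series = lambda t: 5.0 + sum(
            coef[k, 0] * np.sin(2 * np.pi * (k + 1) * t / 0.8 + coef[k, 1]) for k in range(4)
        )
        fine = tawss(series(t_fine)[None, :], t_fine).values[0]
        coarse = tawss(series(t_coarse)[None, :], t_coarse).values[0]
        assert abs(coarse - fine) / fine < 1e-3

    def test_too_few_samples_rejected(self):
        with pytest.raises(DomainError):
            tawss(np.ones((3, 1)), np.array([0.0]))

    def test_positivity(self, labeled_small):
        _, fld = labeled_small
        assert np.all(fld.values > 0)
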