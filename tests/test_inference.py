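"""Inverse problem: force inference, phase extraction, Ma recovery, localization."""

import math

import numpy as np
import pytest

from dyneinloc import (
    MachinModel,
    ModelInconsistencyError,
    NoiseSpec,
    WaveformField,
    WaveSpec,
    analytic_pair,
    extract_phase,
    force_phase,
    generate,
    infer_force,
    localize,
    recover_ma,
    static_force_density,
)
from dyneinloc.core import GridError
from dyneinloc.continuum import ForceField

from conftest import wave_at_ma


class TestInferForce:
    def test_recovers_closed_form_force(self, params):
        """Round trip against the analytic oracle at Ma = 1: rel RMS < 1e-3."""
        wave = wave_at_ma(params, 1.0)
        w, g_true = analytic_pair(wave, params)
        g = infer_force(w, params)
        rms = np.sqrt(np.mean((g.f - g_true.f) ** 2))
        assert rms < 1e-3 * np.sqrt(np.mean(g_true.f**2))

    def test_static_repeated_frames_reduce_to_elastic_inference(self, params):
        """With no motion the inferred force equals the static elastic balance."""
        x = np.linspace(0.0, 10.0, 128, endpoint=False)
        t = np.linspace(0.0, 1.0, 8, endpoint=False)
        y = np.tile(0.1 * np.sin(2 * np.pi * x / 10.0), (8, 1))
        w = WaveformField(x=x, t=t, y=y, periodic_in_x=True, periodic_in_t=True)
        g = infer_force(w, params)
        g_static = static_force_density(w, params)
        assert np.allclose(g.f, g_static.f, atol=1e-9 * np.max(np.abs(g_static.f)))

    def test_zero_waveform_gives_zero_force(self, params):
        x = np.linspace(0.0, 10.0, 128, endpoint=False)
        t = np.linspace(0.0, 0.02, 8, endpoint=False)
        w = WaveformField(x=x, t=t, y=np.zeros((8, 128)),
                          periodic_in_x=True, periodic_in_t=True)
        assert np.allclose(infer_force(w, params).f, 0.0)

    def test_undersampled_input_rejected_with_requirements(self, params):
        wave = wave_at_ma(params, 1.0)
        # 4 wavelengths at 16 points each: dominant mode has < 16 points/wavelength
        w = generate(wave, params, nx_per_wavelength=16, n_wavelengths=1)
        coarse = WaveformField(
            x=w.x, t=w.t, y=np.tile(np.sin(4 * 2 * np.pi * w.x / 10.0), (w.t.size, 1)),
            periodic_in_x=True, periodic_in_t=True,
        )
        with pytest.raises(GridError, match="points per"):
            infer_force(coarse, params)


class TestExtractPhase:
    def test_self_phase_is_zero(self):
        x = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        a = np.sin(x)
        assert extract_phase(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_quadrature_pair_sign_convention(self):
        """sin(kx) trails cos(kx) by a quarter wave: extract_phase(sin, cos) = -pi/2."""
        x = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        assert extract_phase(np.sin(x), np.cos(x)) == pytest.approx(-np.pi / 2)
        assert extract_phase(np.cos(x), np.sin(x)) == pytest.approx(np.pi / 2)

    def test_force_vs_curvature_at_unity_ma(self, params):
        """|phase(f, C)| = 3pi/4 at Ma = 1."""
        from dyneinloc.continuum import curvature_field

        wave = wave_at_ma(params, 1.0)
        w, g = analytic_pair(wave, params)
        C = curvature_field(w)
        assert abs(extract_phase(g.f, C)) == pytest.approx(3 * np.pi / 4, abs=1e-9)

    def test_degenerate_field_rejected(self):
        x = np.zeros(64)
        with pytest.raises(ModelInconsistencyError):
            extract_phase(x, x)


class TestRecoverMa:
    @pytest.mark.parametrize("ma", [0.02, 0.1, 1.0, 10.0])
    def test_clean_recovery_within_five_percent(self, params, ma):
        w = generate(wave_at_ma(params, ma), params)
        assert recover_ma(w, params) == pytest.approx(ma, rel=0.05)

    @pytest.mark.parametrize("ma", [0.1, 1.0])
    def test_clean_recovery_tight(self, params, ma):
        w = generate(wave_at_ma(params, ma), params)
        est = recover_ma(w, params)
        assert ma * 0.95 <= est <= ma * 1.05

    @pytest.mark.parametrize("ma", [0.02, 0.1, 1.0, 10.0])
    def test_noisy_recovery_within_twenty_percent(self, params, ma):
        """1% amplitude noise, 20 seeded realizations: bias and spread stay small."""
        wave = wave_at_ma(params, ma)
        estimates = []
        for seed in range(20):
            w = generate(wave, params, noise=NoiseSpec(sigma=0.01 * wave.y0, seed=seed))
            estimates.append(recover_ma(w, params))
        estimates = np.asarray(estimates)
        assert np.all(np.abs(estimates / ma - 1.0) < 0.20)
        bias = estimates.mean() / ma - 1.0
        spread = estimates.std() / ma
        assert abs(bias) < 0.10
        assert spread < 0.10

    def test_zero_waveform_is_degenerate(self, params):
        x = np.linspace(0.0, 10.0, 128, endpoint=False)
        t = np.linspace(0.0, 0.02, 8, endpoint=False)
        w = WaveformField(x=x, t=t, y=np.zeros((8, 128)),
                          periodic_in_x=True, periodic_in_t=True)
        with pytest.raises(ModelInconsistencyError):
            recover_ma(w, params)


class TestLocalize:
    def test_static_limit_force_extrema_at_curvature_zero_crossings(self, params):
        """Ma << 1: no differential motor activity at the curvature extrema."""
        wave = wave_at_ma(params, 1e-4)
        w, g = analytic_pair(wave, params)
        from dyneinloc.continuum import curvature_field

        C = curvature_field(w)[0]
        f = g.f[0]
        i_f = int(np.argmax(np.abs(f)))
        # curvature at the force extremum is near its zero crossing
        assert abs(C[i_f]) < 0.05 * np.max(np.abs(C))

    def test_drag_limit_dm69_active_in_reverse_bend(self, params):
        """Ma >> 1: the DM6-9 dyneins are the active group inside negative bends."""
        wave = wave_at_ma(params, 1e4)
        w, g = analytic_pair(wave, params)
        report = localize(w, g)
        reverse = [r for r in report.regions if r.bend_class == "reverse"]
        assert reverse and all(r.dominant_group == "DM6-9" for r in reverse)
        principal = [r for r in report.regions if r.bend_class == "principal"]
        assert principal and all(r.dominant_group == "DM1-4" for r in principal)

    @pytest.mark.parametrize("ma", [0.02, 0.1, 1.0, 10.0])
    def test_spatial_lag_matches_phase_formula(self, params, ma):
        """Lag of force behind curvature = (pi - phi)/(2 pi) wavelengths."""
        w, g = analytic_pair(wave_at_ma(params, ma), params)
        report = localize(w, g)
        assert report.spatial_lag == pytest.approx(
            (math.pi - force_phase(ma)) / (2 * math.pi), abs=1e-6
        )

    def test_spatial_lag_monotone_in_ma(self, params):
        lags = []
        for ma in (0.02, 0.1, 1.0, 10.0):
            w, g = analytic_pair(wave_at_ma(params, ma), params)
            lags.append(localize(w, g).spatial_lag)
        assert all(b > a for a, b in zip(lags, lags[1:]))

    def test_flipping_force_sign_flips_labels_and_nothing_else(self, params):
        w, g = analytic_pair(wave_at_ma(params, 1e4), params)
        flipped = ForceField(x=g.x, t=g.t, f=-g.f, periodic_in_x=True)
        r1 = localize(w, g)
        r2 = localize(w, flipped)
        swap = {"DM6-9": "DM1-4", "DM1-4": "DM6-9", "none": "none"}
        assert len(r1.regions) == len(r2.regions)
        for a, b in zip(r1.regions, r2.regions):
            assert (a.x_start, a.x_end, a.bend_class) == (b.x_start, b.x_end, b.bend_class)
            assert b.dominant_group == swap[a.dominant_group]

    def test_bend_classes_partition_the_domain(self, params):
        w, g = analytic_pair(wave_at_ma(params, 1.0), params)
        report = localize(w, g)
        # contiguous, non-overlapping coverage of the grid
        assert report.regions[0].x_start == w.x[0]
        assert report.regions[-1].x_end == w.x[-1]
        for a, b in zip(report.regions, report.regions[1:]):
            assert b.x_start > a.x_end

    def test_mismatched_grids_rejected(self, params):
        w, g = analytic_pair(wave_at_ma(params, 1.0), params)
        bad = ForceField(x=g.x * 2, t=g.t, f=g.f, periodic_in_x=True)
        with pytest.raises(GridError):
            localize(w, bad)


class TestMachinModel:
    def test_fit_recovers_generating_machin_number(self, params):
        wave = wave_at_ma(params, 0.5)
        res = MachinModel(generate(wave, params), params).fit()
        assert res.Ma_estimate == pytest.approx(0.5, rel=0.02)
        assert res.curvature_lag == pytest.approx(math.pi - force_phase(0.5), abs=1e-3)

    def test_from_dataframe_round_trip(self, params):
        from dyneinloc.io import waveform_to_dataframe

        wave = wave_at_ma(params, 1.0)
        w = generate(wave, params)
        model = MachinModel.from_dataframe(waveform_to_dataframe(w), params)
        assert np.allclose(model.waveform.y, w.y)

    def test_summary_reports_key_quantities(self, params):
        res = MachinModel(generate(wave_at_ma(params, 1.0), params), params).fit()
        text = res.summary()
        assert "Machin number estimate" in text
        assert "curvature lag" in text
        assert "bend class" in text

    def test_smoothing_improves_or_preserves_noisy_fit(self, params):
        from dyneinloc import Smoothing

        wave = wave_at_ma(params, 1.0)
        w = generate(wave, params, noise=NoiseSpec(sigma=0.01 * wave.y0, seed=1))
        res_smooth = MachinModel(w, params, smoothing=Smoothing()).fit()
        assert res_smooth.Ma_estimate == pytest.approx(1.0, rel=0.25)

    def test_static_curvature_component_warns(self, params):
        wave = wave_at_ma(params, 1.0)
        w = generate(wave, params)
        bowed = WaveformField(
            x=w.x, t=w.t,
            y=w.y + 0.5 * np.sin(2 * np.pi * w.x / 10.0)[None, :],
            periodic_in_x=True, periodic_in_t=True,
        )
        with pytest.warns(UserWarning, match="static curvature"):
            MachinModel(bowed, params)

    def test_phase_uncertainty_is_reported(self, params):
        wave = wave_at_ma(params, 1.0)
        w = generate(wave, params, noise=NoiseSpec(sigma=0.01 * wave.y0, seed=2))
        res = MachinModel(w, params).fit()
        assert res.phi_std > 0.0
        clean = MachinModel(generate(wave, params), params).fit()
        assert clean.phi_std < res.phi_std
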