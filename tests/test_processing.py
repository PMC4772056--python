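"""Fourier transform, automatic phasing, baseline, referencing, quality."""

import numpy as np
import pytest

import oilnmr as o
from oilnmr.processing import _phase_vector

from conftest import oracle_proton_counts


def _dephase(spectrum, phi0, phi1):
    d = spectrum.complex_data * _phase_vector(spectrum.n_points, phi0, phi1)
    return spectrum.with_data(intensity=d.real, imag=d.imag)


def _recovered_phases(spectrum):
    step = [s for s in spectrum.steps if s.startswith("auto_phase(phi0")][-1]
    parts = step.replace("auto_phase(phi0=", "").replace("deg)", "")
    phi0, phi1 = parts.split("deg, phi1=")
    return float(phi0), float(phi1)


class TestTransform:
    def test_single_exponential_gives_single_peak_at_offset(self, default_params):
        t = np.arange(16384) / default_params.spectral_width_hz
        f_hz = (3.5 - 5.0) * default_params.spectrometer_frequency
        data = np.exp((2j * np.pi * f_hz - np.pi * 1.0) * t)
        spectrum = o.transform(o.RawFID(data, default_params))
        peak_ppm = spectrum.ppm[np.argmax(spectrum.intensity)]
        assert peak_ppm == pytest.approx(3.5, abs=0.001)

    def test_axis_spans_offset_plus_minus_half_width(self, olive_spectrum):
        assert olive_spectrum.ppm.max() == pytest.approx(11.0, abs=0.01)
        assert olive_spectrum.ppm.min() == pytest.approx(-1.0, abs=0.01)
        assert np.all(np.diff(olive_spectrum.ppm) < 0)

    def test_digital_resolution_is_0_11_hz(self, olive_spectrum):
        q = o.quality_metrics(olive_spectrum)
        assert round(q.digital_resolution_hz, 2) == 0.11
        assert olive_spectrum.n_points == 32768

    def test_all_zero_fid_transforms_to_zero_spectrum(self, default_params):
        fid = o.RawFID(np.zeros(16384, complex), default_params)
        assert not np.any(o.transform(fid).intensity)

    def test_zero_fill_below_data_length_rejected(self, default_params):
        fid = o.RawFID(np.zeros(16384, complex), default_params)
        with pytest.raises(ValueError):
            o.transform(fid, zero_fill_to=8192)

    def test_linearity(self, olive_spec, default_params):
        fid = o.synthesize_fid(olive_spec, default_params)
        doubled = o.RawFID(2.0 * fid.data, default_params)
        a = o.transform(fid)
        b = o.transform(doubled)
        assert np.allclose(b.intensity, 2.0 * a.intensity)
        assert np.allclose(b.imag, 2.0 * a.imag)


class TestAutoPhase:
    @pytest.mark.parametrize("phi0, phi1", [(30.0, 10.0), (0.0, 0.0), (-120.0, -35.0)])
    def test_known_phases_recovered_within_one_degree(self, olive_spectrum, phi0, phi1):
        dephased = _dephase(olive_spectrum, -phi0, -phi1)
        rephased = o.auto_phase(dephased)
        r0, r1 = _recovered_phases(rephased)
        assert r0 == pytest.approx(phi0, abs=1.0)
        assert r1 == pytest.approx(phi1, abs=1.0)
        positive = rephased.intensity[rephased.intensity > 0].sum()
        assert positive / np.abs(rephased.intensity).sum() > 0.99

    def test_idempotent_within_half_degree(self, olive_spectrum):
        once = o.auto_phase(_dephase(olive_spectrum, -20.0, -5.0))
        twice = o.auto_phase(once)
        r0, r1 = _recovered_phases(twice)
        assert abs(r0) < 0.5 and abs(r1) < 0.5

    def test_pure_noise_returns_flagged_not_raising(self, default_params):
        rng = np.random.default_rng(0)
        data = rng.standard_normal(16384) + 1j * rng.standard_normal(16384)
        spectrum = o.transform(o.RawFID(data, default_params))
        out = o.auto_phase(spectrum)
        assert "phase_fallback" in out.flags


class TestBaseline:
    def test_linear_ramp_removed_with_integrals_preserved(self, olive_spectrum, regions):
        clean = o.baseline_correct(olive_spectrum)
        ref = o.integrate(clean, regions, line_width_hz=0.68)
        mx = olive_spectrum.intensity.max()
        ramp = np.linspace(0.0, 0.02 * mx, olive_spectrum.n_points) + 0.01 * mx
        ramped = o.baseline_correct(olive_spectrum.with_data(
            intensity=olive_spectrum.intensity + ramp))
        table = o.integrate(ramped, regions, line_width_hz=0.68)
        for signal in ("A", "C", "E", "F", "H", "J"):
            assert table[signal] == pytest.approx(ref[signal], rel=0.005)

    def test_constant_offset_removed(self, olive_spectrum):
        mx = olive_spectrum.intensity.max()
        shifted = olive_spectrum.with_data(intensity=olive_spectrum.intensity + 0.05 * mx)
        corrected = o.baseline_correct(shifted)
        noise_region = corrected.region_mask(9.5, 10.5)
        assert np.abs(corrected.intensity[noise_region]).max() < 1e-3 * mx

    def test_zero_baseline_left_unchanged(self, olive_spectrum):
        corrected = o.baseline_correct(olive_spectrum)
        mx = olive_spectrum.intensity.max()
        assert np.abs(corrected.intensity - olive_spectrum.intensity).max() < 1e-3 * mx


class TestReferencing:
    def test_injected_offset_recovered(self, olive_spectrum):
        shifted = olive_spectrum.with_data(ppm=olive_spectrum.ppm + 0.05)
        referenced = o.reference_to_tms(shifted)
        assert referenced.ppm[0] - olive_spectrum.ppm[0] == pytest.approx(0.0, abs=1e-3)
        assert "tms_missing" not in referenced.flags

    def test_idempotent(self, olive_spectrum):
        once = o.reference_to_tms(olive_spectrum)
        twice = o.reference_to_tms(once)
        assert np.allclose(once.ppm, twice.ppm, atol=1e-6)

    def test_spectrum_without_tms_flagged_axis_unchanged(self):
        spec = o.OilSpec.preset("olive", include_tms=False)
        spectrum = o.synthesize_spectrum(spec)
        referenced = o.reference_to_tms(spectrum)
        assert "tms_missing" in referenced.flags
        assert np.array_equal(referenced.ppm, spectrum.ppm)


class TestQuality:
    def test_noiseless_spectrum_reports_infinite_snr(self, olive_spectrum):
        q = o.quality_metrics(olive_spectrum)
        assert np.isinf(q.snr_b) and q.snr_ok

    def test_linewidth_matches_generator_setting(self, olive_spectrum):
        q = o.quality_metrics(olive_spectrum)
        assert q.linewidth_tms_hz == pytest.approx(0.68, rel=0.05)
        assert q.resolution_ok

    def test_snr_against_construction(self):
        spec = o.OilSpec.preset("picual")
        sigma = o.noise_sigma_for_snr(spec, snr=250)
        noisy = o.OilSpec.preset("picual", noise_sigma=sigma, seed=3)
        q = o.quality_metrics(o.synthesize_spectrum(noisy, noiseless=False))
        assert q.snr_b == pytest.approx(250, rel=0.10)

    def test_missing_noise_window_rejected(self, default_params):
        params = o.AcquisitionParameters(spectral_width=6.0, transmitter_offset=2.0,
                                         acquisition_time=0)
        t = np.arange(16384) / params.spectral_width_hz
        fid = o.RawFID(np.exp((2j * np.pi * 100.0 - np.pi) * t), params)
        with pytest.raises(ValueError, match="noise window"):
            o.quality_metrics(o.transform(fid))


class TestExperimentDuration:
    @pytest.mark.parametrize(
        "ns, ds, aq, d1, expected",
        [
            (8, 2, 4.56, 4.0, 86),  # the protocol's 1 min 26 s
            (16, 2, 4.56, 4.0, 154),
            (1, 0, 1.0, 0.0, 1),
        ],
    )
    def test_total_time_rounded_to_seconds(self, ns, ds, aq, d1, expected):
        params = o.AcquisitionParameters(
            n_scans=ns, n_dummy_scans=ds, acquisition_time=aq, recycle_delay=d1,
            n_complex_points=16384,
        )
        assert o.experiment_duration(params) == expected


class TestFullChain:
    def test_noiseless_pipeline_reproduces_catalog_areas(self, regions):
        """Every region integral lands within 1% of the proton-count truth
        (linseed: all ten signals carry at least one proton)."""
        spec = o.OilSpec.preset("linseed")
        spectrum, quality = o.process(o.synthesize_fid(spec))
        table = o.normalize(
            o.integrate(spectrum, regions, line_width_hz=quality.linewidth_tms_hz),
            "f6",
        )
        truth = oracle_proton_counts(*spec.fractions)
        for signal, expected in truth.items():
            assert table[signal] == pytest.approx(expected, rel=0.01), signal
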