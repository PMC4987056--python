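"""Preprocessing chain: phasing, baselines, referencing, TSP metrics."""

import dataclasses

import numpy as np
import pytest

from asphyxomics.preprocess import (PLASMA_ANCHOR, PreprocessConfig,
                                    adaptive_baseline, clip, clip_and_excise,
                                    measure_tsp_fwhm, normalize_to_tsp,
                                    phase_correct_zero_order,
                                    preprocess_pipeline, reference_axis,
                                    subtract_linear_baselines)
from asphyxomics.render import render_spectrum
from asphyxomics.spectrum import RegionSet, Spectrum, default_regions


def rotate(s, deg):
    return dataclasses.replace(
        s, intensity=s.intensity * np.exp(1j * np.deg2rad(deg)))


@pytest.fixture(scope="module")
def clean_spectrum(plasma_panel, acq):
    return render_spectrum({"Lactate": 2.9, "Glucose": 6.0}, plasma_panel,
                           acq, seed=0, noiseless=True)


class TestPhaseCorrection:
    def test_zero_phase_recovered(self, clean_spectrum):
        out = phase_correct_zero_order(clean_spectrum)
        assert abs(out.qc["phase_deg"]) < 0.5

    def test_thirty_degree_round_trip(self, clean_spectrum):
        out = phase_correct_zero_order(rotate(clean_spectrum, 30.0))
        assert out.qc["phase_deg"] == pytest.approx(-30.0, abs=0.5)
        # TSP real-part area restored
        m = out.window(-0.05, 0.05)
        ref = clean_spectrum.window(-0.05, 0.05)
        a1 = np.trapezoid(out.real[m], out.ppm[m])
        a0 = np.trapezoid(clean_spectrum.real[ref], clean_spectrum.ppm[ref])
        assert a1 == pytest.approx(a0, rel=1e-3)

    def test_idempotence(self, clean_spectrum):
        once = phase_correct_zero_order(rotate(clean_spectrum, 30.0))
        twice = phase_correct_zero_order(once)
        assert abs(twice.qc["phase_deg"] - once.qc["phase_deg"]) < 0.5

    def test_real_input_warns_and_passes_through(self, clean_spectrum):
        real = dataclasses.replace(clean_spectrum,
                                   intensity=clean_spectrum.real)
        with pytest.warns(UserWarning, match="real"):
            out = phase_correct_zero_order(real)
        assert np.array_equal(out.intensity, real.intensity)

    def test_empty_window_errors(self, clean_spectrum):
        with pytest.raises(ValueError):
            phase_correct_zero_order(clean_spectrum, tsp_window=(12.0, 13.0))


class TestLinearBaselines:
    def test_zero_baseline_unchanged(self, clean_spectrum):
        out = subtract_linear_baselines(clean_spectrum, (4.55, 4.95))
        resid = out.real - clean_spectrum.real
        assert np.abs(resid).max() < 1e-2 * clean_spectrum.real.max()

    def test_two_sided_tilt_removed(self, plasma_panel, acq):
        s = render_spectrum({"Lactate": 2.9}, plasma_panel, acq, seed=0,
                            noiseless=True)
        y = s.real.copy()
        lo = s.ppm < 4.55
        hi = s.ppm >= 4.95
        y[lo] += 3.0 + 2.0 * s.ppm[lo]
        y[hi] += -5.0 - 1.0 * s.ppm[hi]
        tilted = dataclasses.replace(s, intensity=y)
        out = subtract_linear_baselines(tilted, (4.55, 4.95))
        quiet = (s.ppm > 6.5) & (s.ppm < 8.0)
        rms = np.sqrt(np.mean(out.real[quiet] ** 2))
        amp = np.abs(-5.0 - 1.0 * s.ppm[hi]).max()
        assert rms < 0.01 * amp

    def test_water_covering_a_side_errors(self, clean_spectrum):
        with pytest.raises(ValueError):
            subtract_linear_baselines(clean_spectrum, (-2.0, 4.95))


class TestReferencing:
    def test_aligned_spectrum_zero_shift(self, clean_spectrum):
        s = phase_correct_zero_order(clean_spectrum)
        out = reference_axis(s, PLASMA_ANCHOR)
        assert abs(out.qc["ppm_shift"]) <= 2 * s.step

    def test_injected_offset_recovered(self, plasma_panel, acq):
        for offset in (+0.02, -0.02):
            s = render_spectrum({"Glucose": 6.0}, plasma_panel, acq, seed=0,
                                noiseless=True)
            shifted = Spectrum(ppm=s.ppm + offset, intensity=s.intensity,
                               material=s.material)
            out = reference_axis(shifted, PLASMA_ANCHOR)
            assert out.qc["ppm_shift"] == pytest.approx(-offset,
                                                        abs=2 * s.step)

    def test_missing_anchor_errors(self, plasma_panel, acq):
        s = render_spectrum({}, plasma_panel, acq, seed=0, noiseless=True,
                            with_water=False)
        with pytest.raises(ValueError, match="5.234"):
            reference_axis(phase_correct_zero_order(s), PLASMA_ANCHOR)


class TestClipExcise:
    def test_clip_only_with_empty_regions(self, clean_spectrum):
        out = clip(clean_spectrum, (-0.5, 9.0))
        assert out.ppm.min() >= -0.5 and out.ppm.max() < 9.0

    def test_default_regions_removed(self, clean_spectrum):
        out = clip_and_excise(clean_spectrum, default_regions("plasma"))
        assert not out.window(4.55, 4.95).any()
        assert not out.window(-0.2, 0.2).any()

    def test_point_count_bookkeeping(self, clean_spectrum):
        regions = default_regions("plasma")
        removed = clean_spectrum.window(*regions.water).sum() \
            + clean_spectrum.window(*regions.tsp).sum() \
            + (~clean_spectrum.window(*regions.clip)).sum()
        out = clip_and_excise(clean_spectrum, regions)
        assert out.ppm.size == clean_spectrum.ppm.size - removed

    def test_excising_everything_errors(self, clean_spectrum):
        with pytest.raises(ValueError):
            clip_and_excise(clean_spectrum,
                            RegionSet(clip=(-0.5, 9.0), water=(-0.5, 9.0),
                                      tsp=(-0.5, 9.0)))


class TestNormalization:
    def test_tsp_area_one_after(self, clean_spectrum):
        s = phase_correct_zero_order(clean_spectrum)
        out = normalize_to_tsp(s)
        assert out.qc["tsp_area"] == 1.0
        # re-measuring the TSP area of the normalized spectrum gives 1
        again = normalize_to_tsp(out)
        assert again.qc["tsp_area_raw"] == pytest.approx(1.0, rel=1e-6)

    def test_scale_invariance(self, clean_spectrum):
        s = phase_correct_zero_order(clean_spectrum)
        doubled = dataclasses.replace(s, intensity=2 * s.intensity)
        a = normalize_to_tsp(s)
        b = normalize_to_tsp(doubled)
        assert np.allclose(a.real, b.real, rtol=1e-9)

    def test_negative_area_errors(self, clean_spectrum):
        flipped = dataclasses.replace(clean_spectrum,
                                      intensity=-clean_spectrum.real)
        with pytest.raises(ValueError):
            normalize_to_tsp(flipped)


class TestTspFwhm:
    def test_lorentzian_closed_form(self, plasma_panel, acq):
        s = render_spectrum({}, plasma_panel, acq, seed=0, noiseless=True,
                            with_water=False)
        fwhm = measure_tsp_fwhm(phase_correct_zero_order(s))
        assert fwhm == pytest.approx(acq.tsp_linewidth, abs=s.step)

    def test_broadening_factor_round_trip(self, plasma_panel, acq):
        f = []
        for b in (1.0, 1.5):
            s = render_spectrum({}, plasma_panel, acq, seed=0, noiseless=True,
                                tsp_broadening=b, with_water=False)
            f.append(measure_tsp_fwhm(phase_correct_zero_order(s)))
        assert f[1] / f[0] == pytest.approx(1.5, rel=0.05)

    def test_scale_invariant(self, clean_spectrum):
        s = phase_correct_zero_order(clean_spectrum)
        doubled = dataclasses.replace(s, intensity=2 * s.intensity)
        assert measure_tsp_fwhm(s) == pytest.approx(measure_tsp_fwhm(doubled))


class TestAdaptiveBaseline:
    def test_flat_input_unchanged(self, plasma_panel, acq):
        from asphyxomics.quantify import peak_mask_windows
        s = render_spectrum({"Lactate": 2.9, "Glucose": 6.0}, plasma_panel,
                            acq, seed=0, noiseless=True, with_water=False)
        out = adaptive_baseline(
            s, peak_windows=peak_mask_windows(plasma_panel, acq))
        # zero background: deviation limited to subtracted wing floors
        assert np.abs(out.real - s.real).max() < 0.01 * s.real.max()

    def test_broad_hump_removed_peaks_kept(self, plasma_panel, acq, rng):
        s = render_spectrum({"Lactate": 2.9, "Glucose": 6.0}, plasma_panel,
                            acq, seed=0, noiseless=True, with_water=False)
        hump = 50.0 * np.exp(-0.5 * ((s.ppm - 3.0) / 0.5) ** 2)
        dirty = dataclasses.replace(s, intensity=s.real + hump)
        out = adaptive_baseline(dirty)
        quiet = (s.ppm > 2.0) & (s.ppm < 4.0) & (np.abs(s.real) < 1.0)
        resid = out.real[quiet]
        assert np.sqrt(np.mean(resid ** 2)) < 0.05 * hump.max()
        # narrow peak areas preserved within 10%
        m = (s.ppm > 1.30) & (s.ppm < 1.36)
        a0 = np.trapezoid(s.real[m], s.ppm[m])
        a1 = np.trapezoid(out.real[m], out.ppm[m])
        assert a1 == pytest.approx(a0, rel=0.10)


class TestPipeline:
    @staticmethod
    def config(plasma_panel, acq):
        from asphyxomics.quantify import peak_mask_windows
        return PreprocessConfig(material="plasma",
                                peak_windows=peak_mask_windows(plasma_panel,
                                                               acq))

    def test_history_grows_one_entry_per_step(self, clean_spectrum):
        out = preprocess_pipeline(clean_spectrum,
                                  PreprocessConfig(material="plasma"))
        names = [h[0] for h in out.history]
        assert names == ["phase_correct_zero_order",
                         "subtract_linear_baselines", "reference_axis",
                         "clip", "normalize_to_tsp", "adaptive_baseline",
                         "clip_and_excise"]

    def test_rerun_on_own_output_is_stable(self, clean_spectrum,
                                           plasma_panel, acq):
        cfg = self.config(plasma_panel, acq)
        once = preprocess_pipeline(clean_spectrum, cfg)
        with pytest.warns(UserWarning):
            twice = preprocess_pipeline(once, cfg)
        scale = np.abs(once.real).max()
        diff = np.interp(once.ppm, twice.ppm, twice.real) - once.real
        # intensities change by < 0.1% of the spectrum scale (RMS); the
        # worst single point (at an excision-gap edge) stays below 1%
        assert np.sqrt(np.mean(diff ** 2)) < 1e-3 * scale
        assert np.abs(diff).max() < 1e-2 * scale

    def test_global_gain_invariance_end_to_end(self, clean_spectrum,
                                               plasma_panel, acq):
        cfg = self.config(plasma_panel, acq)
        a = preprocess_pipeline(clean_spectrum, cfg)
        doubled = dataclasses.replace(clean_spectrum,
                                      intensity=2 * clean_spectrum.intensity)
        b = preprocess_pipeline(doubled, cfg)
        scale = np.abs(a.real).max()
        assert np.abs(a.real - b.real).max() < 1e-5 * scale
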