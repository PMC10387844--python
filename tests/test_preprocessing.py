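"""Baselining, normalization, resampling and replicate averaging."""

import numpy as np
import pytest

import ftirquant as fq
from ftirquant.errors import (CoverageError, NormalizationError, RangeError,
                              ValidationError)
from ftirquant.preprocessing import DEFAULT_REGIONS

LIPID = DEFAULT_REGIONS["lipid"]
FINGER = DEFAULT_REGIONS["fingerprint"]


def _gauss(grid, center, fwhm=15.0, amp=1.0):
    return amp * np.exp(-4 * np.log(2) * ((grid - center) / fwhm) ** 2)


GRID = np.arange(450.0, 4000.0, 4.0)


class TestBaseline:
    def test_straight_line_maps_to_zero(self):
        s = fq.Spectrum("line", "", GRID, 0.3 + 1e-4 * GRID)
        p = fq.baseline_subtract(s, LIPID)
        assert np.allclose(p.absorbance, 0.0, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 1, GRID.size)
        s1 = fq.Spectrum("a", "", GRID, base)
        s2 = fq.Spectrum("b", "", GRID, base + 0.7 - 3e-4 * GRID)
        p1 = fq.baseline_subtract(s1, FINGER)
        p2 = fq.baseline_subtract(s2, FINGER)
        assert np.allclose(p1.absorbance, p2.absorbance, atol=1e-10)

    def test_gaussian_preserved_when_anchors_outside_tails(self):
        # anchors sit far outside +-4 sigma, so the subtracted line is ~0
        trace = _gauss(GRID, 1184.0, fwhm=15.0)
        s = fq.Spectrum("g", "", GRID, trace)
        p = fq.baseline_subtract(s, FINGER)
        mask = (GRID >= FINGER.lo) & (GRID <= FINGER.hi)
        assert np.max(np.abs(p.absorbance - trace[mask])) < 1e-6

    def test_anchor_values_near_zero(self):
        # anchors chosen on grid points so the restricted trace contains them
        region = fq.AnalysisRegion("lipid", 2802.0, 3018.0, 2802.0, 3018.0)
        rng = np.random.default_rng(1)
        s = fq.Spectrum("r", "", GRID, rng.uniform(0, 1, GRID.size))
        p = fq.baseline_subtract(s, region)
        for a in (region.anchor_lo, region.anchor_hi):
            v = np.interp(a, p.wavenumbers, p.absorbance)
            assert abs(v) <= 1e-12 * np.abs(p.absorbance).max() + 1e-12

    def test_missing_coverage_names_span(self):
        grid = np.arange(1000.0, 4000.0, 4.0)
        s = fq.Spectrum("short", "", grid, np.zeros(grid.size))
        with pytest.raises(CoverageError, match="890"):
            fq.baseline_subtract(s, FINGER)


class TestNormalize:
    # grid aligned so 2924 falls on a sample: the apex is read exactly
    ALIGNED = np.arange(2700.0, 3101.0, 4.0)

    def test_reference_apex_becomes_one(self):
        GRID = self.ALIGNED
        s = fq.Spectrum("h", "", GRID, _gauss(GRID, 2924.0, amp=0.5))
        p = fq.normalize_to_band(fq.baseline_subtract(s, LIPID),
                                 fq.DEFAULT_CATALOG)
        ref = fq.measure_band(p, {b.name: b for b in fq.DEFAULT_CATALOG}["ch2_asym"])
        assert ref.intensity == pytest.approx(1.0, abs=1e-9)
        assert p.normalization_factor == pytest.approx(0.5, rel=1e-6)

    def test_idempotent(self):
        s = fq.Spectrum("h", "", GRID, _gauss(GRID, 2924.0, amp=0.5))
        p1 = fq.normalize_to_band(fq.baseline_subtract(s, LIPID),
                                  fq.DEFAULT_CATALOG)
        p2 = fq.normalize_to_band(p1, fq.DEFAULT_CATALOG)
        assert np.allclose(p1.absorbance, p2.absorbance, atol=1e-12)

    def test_two_band_ratio_unchanged(self):
        trace = _gauss(GRID, 2924.0, amp=0.8) + _gauss(GRID, 2852.0, amp=0.2)
        s = fq.Spectrum("two", "", GRID, trace)
        p0 = fq.baseline_subtract(s, LIPID)
        p1 = fq.normalize_to_band(p0, fq.DEFAULT_CATALOG)
        cat = {b.name: b for b in fq.DEFAULT_CATALOG}

        def ratio(p):
            return (fq.measure_band(p, cat["ch2_sym"]).intensity
                    / fq.measure_band(p, cat["ch2_asym"]).intensity)

        assert ratio(p1) == pytest.approx(ratio(p0), rel=1e-12)

    def test_degenerate_spectrum_rejected(self):
        s = fq.Spectrum("flat", "", GRID, np.zeros(GRID.size))
        with pytest.raises(NormalizationError):
            fq.normalize_to_band(fq.baseline_subtract(s, LIPID),
                                 fq.DEFAULT_CATALOG)


class TestResample:
    def test_identity_on_own_grid(self):
        rng = np.random.default_rng(2)
        s = fq.Spectrum("i", "", GRID, rng.normal(size=GRID.size))
        r = fq.resample(s, GRID)
        assert np.array_equal(r.absorbance, s.absorbance)

    def test_line_exact_anywhere(self):
        s = fq.Spectrum("l", "", GRID, 2.0 - 1e-3 * GRID)
        new = np.linspace(500.0, 3900.0, 777)
        r = fq.resample(s, new)
        assert np.allclose(r.absorbance, 2.0 - 1e-3 * new, atol=1e-12)

    def test_interpolation_error_bound_for_sine(self):
        h = 0.5
        dense = np.arange(1000.0, 1100.0 + h / 2, h)
        f = np.sin(dense / 5.0)
        s = fq.Spectrum("s", "", dense, f)
        mid = dense[:-1] + h / 2  # worst case: midpoints
        r = fq.resample(s, mid)
        bound = h ** 2 * (1 / 25.0) / 8.0  # h^2 max|f''| / 8
        assert np.max(np.abs(r.absorbance - np.sin(mid / 5.0))) <= bound

    def test_extrapolation_rejected(self):
        s = fq.Spectrum("e", "", GRID, np.zeros(GRID.size))
        with pytest.raises(RangeError):
            fq.resample(s, np.array([400.0, 500.0]))


class TestAverageGroup:
    def test_identical_replicates_average_to_themselves(self):
        trace = _gauss(GRID, 1100.0, fwhm=20.0)
        reps = [fq.Spectrum(f"r{i}", "g", GRID, trace) for i in range(3)]
        avg = fq.average_group(fq.SpectrumGroup("g", reps), FINGER)
        p = fq.baseline_subtract(reps[0], FINGER)
        assert np.allclose(avg.absorbance, p.absorbance, atol=1e-12)

    def test_mirror_perturbations_cancel(self):
        base = _gauss(GRID, 1100.0, fwhm=20.0)
        d = 0.05 * np.sin(GRID / 7.0)
        reps = [fq.Spectrum("p", "g", GRID, base + d),
                fq.Spectrum("m", "g", GRID, base - d)]
        avg = fq.average_group(fq.SpectrumGroup("g", reps), FINGER)
        ref = fq.baseline_subtract(fq.Spectrum("b", "g", GRID, base), FINGER)
        assert np.allclose(avg.absorbance, ref.absorbance, atol=1e-10)

    def test_planted_apexes_average_to_mean(self):
        # 1102 cm^-1 sits on the sampling grid, so apexes are read exactly
        reps = [fq.Spectrum(f"r{a}", "g", GRID, _gauss(GRID, 1102.0, 20.0, a))
                for a in (0.9, 1.0, 1.1)]
        avg = fq.average_group(fq.SpectrumGroup("g", reps), FINGER)
        bd = fq.BandDef("test", "", 1102.0, 8.0, "fingerprint")
        m = fq.measure_band(avg, bd)
        assert m.intensity == pytest.approx(1.0, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            fq.SpectrumGroup("g", [])

    def test_measure_then_average_equals_average_then_measure(self):
        # intensity at a fixed wavenumber is linear, so the order of
        # averaging and evaluation must not matter on noiseless data
        reps = [fq.Spectrum(f"r{a}", "g", GRID, _gauss(GRID, 1100.0, 20.0, a))
                for a in (0.5, 1.0, 1.5)]
        avg = fq.average_group(fq.SpectrumGroup("g", reps), FINGER)
        nu = 1104.0
        individual = [
            np.interp(nu, p.wavenumbers, p.absorbance)
            for p in (fq.baseline_subtract(s, FINGER) for s in reps)
        ]
        pooled = np.interp(nu, avg.wavenumbers, avg.absorbance)
        assert pooled == pytest.approx(np.mean(individual), abs=1e-9)
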