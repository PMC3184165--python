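"""Spectral chain: baseline, normalization, alignment, detection,
binning, integration — each checked against constructed signals or
independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.pipeline import Pipeline

from pdynims.model import IMSSection, Spectrum
from pdynims.preprocess import (
    BinDefinition,
    ConvexHullBaseline,
    Peak,
    PeakBinner,
    SpectrumAligner,
    TICNormalizer,
    align_spectra,
    baseline_convex_hull,
    bin_peaks,
    detect_peaks,
    integrate_areas,
    local_background_noise,
    tic_normalize,
)


def _gauss(mz, center, amp, sd):
    return amp * np.exp(-0.5 * ((mz - center) / sd) ** 2)


class TestBaseline:
    def test_constant_maps_to_zero(self):
        mz = 500 + np.arange(50) * 0.1
        out = baseline_convex_hull(Spectrum(mz, np.full(50, 7.0)))
        assert np.allclose(out.intensity, 0.0)

    def test_linear_ramp_maps_to_zero(self):
        mz = 500 + np.arange(50) * 0.1
        out = baseline_convex_hull(Spectrum(mz, 2.0 * mz + 5.0))
        assert np.allclose(out.intensity, 0.0, atol=1e-9)

    def test_gaussian_on_ramp_recovers_amplitude(self):
        mz = 500 + np.arange(2001) * 0.01
        amp = 40.0
        signal = 0.5 * (mz - 500) + 3.0 + _gauss(mz, 510.0, amp, 0.2)
        out = baseline_convex_hull(Spectrum(mz, signal))
        assert out.intensity.max() == pytest.approx(amp, rel=0.01)

    def test_endpoints_zero_and_nonnegative(self, rng):
        mz = 500 + np.arange(500) * 0.05
        y = rng.uniform(0, 10, 500) + 50
        out = baseline_convex_hull(Spectrum(mz, y))
        assert out.intensity[0] == 0.0 and out.intensity[-1] == 0.0
        assert np.all(out.intensity >= 0)

    def test_idempotent(self, rng):
        mz = 500 + np.arange(300) * 0.05
        y = rng.uniform(0, 10, 300) + _gauss(mz, 507, 30, 0.2)
        once = baseline_convex_hull(Spectrum(mz, y))
        twice = baseline_convex_hull(once)
        assert np.allclose(once.intensity, twice.intensity, atol=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            baseline_convex_hull(Spectrum(np.array([500.0, 501.0]), np.array([1.0, 2.0])))


class TestTICNormalize:
    def test_proportional_spectra_collapse(self):
        mz = 500 + np.arange(10) * 0.5
        y = np.arange(10.0) + 1
        a = tic_normalize(Spectrum(mz, y), 1.0)
        b = tic_normalize(Spectrum(mz, 7.3 * y), 1.0)
        assert np.allclose(a.intensity, b.intensity)

    def test_divides_by_tic(self):
        mz = 500 + np.arange(4) * 0.5
        out = tic_normalize(Spectrum(mz, np.array([1.0, 2.0, 3.0, 4.0])), 1.0)
        assert np.allclose(out.intensity, np.array([0.1, 0.2, 0.3, 0.4]))

    def test_target_tic_reached_exactly(self, rng):
        mz = 500 + np.arange(100) * 0.5
        out = tic_normalize(Spectrum(mz, rng.uniform(0, 5, 100)), 42.0)
        assert out.tic == pytest.approx(42.0, rel=1e-9)

    def test_zero_tic_rejected(self):
        mz = 500 + np.arange(4) * 0.5
        with pytest.raises(ValueError, match="zero TIC"):
            tic_normalize(Spectrum(mz, np.zeros(4)), 1.0)

    def test_idempotent_at_fixed_target(self, rng):
        mz = 500 + np.arange(50) * 0.5
        once = tic_normalize(Spectrum(mz, rng.uniform(0, 5, 50)), 10.0)
        twice = tic_normalize(once, 10.0)
        assert np.allclose(once.intensity, twice.intensity)


class TestAlignment:
    REFS = [712.3777, 840.4726]

    def _spectrum(self, shift=0.0):
        mz = 700 + np.arange(4001) * 0.05
        y = sum(_gauss(mz, r + shift, 100.0, 0.15) for r in self.REFS) + 1.0
        return Spectrum(mz, y)

    def test_planted_shift_recovered(self):
        _aligned, shifts, warns = align_spectra([self._spectrum(0.40)], self.REFS, 1.0)
        assert shifts[0] == pytest.approx(0.40, abs=0.05)
        assert not warns[0]

    def test_zero_shift_recovered(self):
        _aligned, shifts, _ = align_spectra([self._spectrum(0.0)], self.REFS, 1.0)
        assert abs(shifts[0]) <= 0.05

    def test_shift_beyond_max_is_clamped_with_warning(self):
        _aligned, shifts, warns = align_spectra([self._spectrum(2.0)], self.REFS, 1.0)
        assert abs(shifts[0]) <= 1.0
        assert warns[0]

    def test_no_reference_in_range_returns_unshifted(self):
        mz = 500 + np.arange(100) * 0.1
        spec = Spectrum(mz, np.ones(100))
        aligned, shifts, warns = align_spectra([spec], [2000.0], 1.0)
        assert warns[0] and shifts[0] == 0.0
        assert np.array_equal(aligned[0].intensity, spec.intensity)

    def test_alignment_commutes_with_normalization(self):
        spec = self._spectrum(0.3)
        a1 = align_spectra([tic_normalize(spec, 5.0)], self.REFS, 1.0)[0][0]
        a2 = tic_normalize(align_spectra([spec], self.REFS, 1.0)[0][0], 5.0)
        # shift estimation is scale-invariant, interpolation is linear
        assert np.allclose(a1.intensity, a2.intensity, rtol=1e-6, atol=1e-9)


def oracle_detect(spectrum, snr_min=3.0, window=101):
    """Exhaustive reference detector: naive sliding-window median/MAD and a
    scan over every strict local maximum."""
    y = spectrum.intensity
    n = y.size
    w = min(window, n)
    if w % 2 == 0:
        w -= 1
    w = max(w, 3)
    half = w // 2
    med = np.empty(n)
    for i in range(n):
        lo, hi = i - half, i + half + 1
        idx = np.arange(lo, hi)
        idx = np.where(idx < 0, -idx - 1, idx)  # reflect
        idx = np.where(idx >= n, 2 * n - idx - 1, idx)
        med[i] = np.median(y[idx])
    mad = np.empty(n)
    dev = np.abs(y - med)
    for i in range(n):
        lo, hi = i - half, i + half + 1
        idx = np.arange(lo, hi)
        idx = np.where(idx < 0, -idx - 1, idx)
        idx = np.where(idx >= n, 2 * n - idx - 1, idx)
        mad[i] = np.median(dev[idx])
    noise = 1.4826 * mad
    hits = []
    for i in range(1, n - 1):
        if y[i] > y[i - 1] and y[i] > y[i + 1]:
            height = y[i] - med[i]
            snr = height / noise[i] if noise[i] > 0 else (np.inf if height > 0 else 0)
            if snr > snr_min:
                hits.append(i)
    return hits


class TestDetectPeaks:
    def test_flat_zero_spectrum_empty(self):
        mz = 500 + np.arange(100) * 0.1
        assert detect_peaks(Spectrum(mz, np.zeros(100))) == []

    def test_single_gaussian_over_noise(self, rng):
        mz = 500 + np.arange(1000) * 0.1
        noise_sd = 1.0
        y = np.clip(rng.normal(0, noise_sd, 1000), 0, None)
        y += _gauss(mz, 550.0, 10 * noise_sd, 0.3)
        spec = Spectrum(mz, y)
        peaks = detect_peaks(spec, snr_min=3.0)
        near = [p for p in peaks if abs(p.apex_mz - 550.0) <= 0.1]
        assert len(near) == 1
        # oracle agreement on the same array
        oracle = oracle_detect(spec)
        assert sorted(p.apex_mz for p in peaks) == sorted(mz[i] for i in oracle)

    def test_pure_noise_count_matches_exhaustive_oracle(self, rng):
        mz = 500 + np.arange(1000) * 0.1
        y = np.abs(rng.normal(0, 1.0, 1000))
        spec = Spectrum(mz, y)
        peaks = detect_peaks(spec, snr_min=3.0)
        assert len(peaks) == len(oracle_detect(spec))

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(50, 2000))
    def test_oracle_equivalence_property(self, seed, n):
        r = np.random.default_rng(seed)
        mz = 500 + np.arange(n) * 0.1
        y = np.abs(r.normal(0, 1, n)) + _gauss(mz, mz[n // 2], r.uniform(0, 20), 0.3)
        spec = Spectrum(mz, y)
        ours = sorted(p.apex_mz for p in detect_peaks(spec, snr_min=3.0))
        oracle = sorted(mz[i] for i in oracle_detect(spec, snr_min=3.0))
        assert ours == oracle

    def test_bounds_bracket_apex(self, rng):
        mz = 500 + np.arange(500) * 0.1
        y = np.abs(rng.normal(0, 1, 500)) + _gauss(mz, 525, 30, 0.3)
        for p in detect_peaks(Spectrum(mz, y)):
            assert p.left_mz <= p.apex_mz <= p.right_mz
            assert p.snr > 3.0


def oracle_single_linkage(apexes, tol):
    """Cluster sorted apexes: merge while the gap to the next is <= tol."""
    apexes = np.sort(np.asarray(apexes))
    clusters = [[apexes[0]]]
    for a in apexes[1:]:
        if a - clusters[-1][-1] <= tol:
            clusters[-1].append(a)
        else:
            clusters.append([a])
    return [np.mean(c) for c in clusters]


def _peaklist(apexes):
    return [Peak(a, 1.0, a - 0.1, a + 0.1, 10.0) for a in apexes]


class TestBinPeaks:
    def test_identical_apexes_one_bin_each(self):
        pls = [_peaklist([712.38, 981.56]) for _ in range(5)]
        bins = bin_peaks(pls, tol=0.3)
        assert [b.center for b in bins] == pytest.approx([712.38, 981.56])
        assert [b.count for b in bins] == [5, 5]

    def test_jittered_cluster_single_bin(self, rng):
        apexes = 712.38 + rng.uniform(-0.05, 0.05, 50)
        bins = bin_peaks([_peaklist([a]) for a in apexes], tol=0.15)
        assert len(bins) == 1
        assert bins[0].center == pytest.approx(712.38, abs=0.02)

    def test_two_populations_two_bins(self):
        pls = [_peaklist([712.38]), _peaklist([712.80])]
        bins = bin_peaks(pls, tol=0.15)
        assert len(bins) == 2

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_single_linkage_on_separated_clusters(self, seed):
        """For clusters tighter than tol and separated by more than tol,
        greedy running-mean binning equals single-linkage clustering."""
        r = np.random.default_rng(seed)
        centers = 600 + np.cumsum(r.uniform(1.0, 5.0, r.integers(2, 8)))
        apexes = np.concatenate(
            [c + r.uniform(-0.05, 0.05, r.integers(1, 10)) for c in centers]
        )
        r.shuffle(apexes)
        bins = bin_peaks([_peaklist([a]) for a in apexes], tol=0.15)
        oracle = oracle_single_linkage(apexes, 0.15)
        assert len(bins) == len(oracle)
        assert [b.center for b in bins] == pytest.approx(oracle)

    def test_partition_and_non_overlap(self, rng):
        apexes = np.sort(rng.uniform(600, 650, 100))
        bins = bin_peaks([_peaklist([a]) for a in apexes], tol=0.3)
        assert sum(b.count for b in bins) == 100
        for b1, b2 in zip(bins, bins[1:]):
            assert b1.center + b1.half_width <= b2.center - b2.half_width + 1e-12

    def test_empty_input(self):
        assert bin_peaks([[], []], tol=0.3) == []


class TestIntegrateAreas:
    def _section(self, spectra):
        return IMSSection(
            section_id="s",
            animal_id="a",
            run_id=1,
            coords=np.array([(i, 0) for i in range(len(spectra))]),
            spectra=spectra,
            hemispheres=["intact"] * len(spectra),
        )

    def test_unit_triangle_area(self):
        mz = np.array([711.0, 711.5, 712.0, 712.5, 713.0, 713.5])
        y = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0])  # triangle base 1 Da at 712
        sec = self._section([Spectrum(mz, y)])
        table = integrate_areas(sec, [BinDefinition(712.0, 0.5, 1)])
        assert table.areas[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_gaussian_area_matches_analytic(self):
        mz = 700 + np.arange(4000) * 0.01
        amp, sd = 30.0, 0.1
        sec = self._section([Spectrum(mz, _gauss(mz, 712.0, amp, sd))])
        table = integrate_areas(sec, [BinDefinition(712.0, 2.0, 1)])
        assert table.areas[0, 0] == pytest.approx(amp * sd * np.sqrt(2 * np.pi), rel=0.01)

    def test_zero_window_zero_area(self):
        mz = 700 + np.arange(100) * 0.1
        sec = self._section([Spectrum(mz, np.zeros(100))])
        table = integrate_areas(sec, [BinDefinition(705.0, 0.5, 1)])
        assert table.areas[0, 0] == 0.0

    def test_bin_outside_range_is_missing(self):
        mz = 700 + np.arange(100) * 0.1
        sec = self._section([Spectrum(mz, np.ones(100))])
        table = integrate_areas(sec, [BinDefinition(2000.0, 0.5, 1)])
        assert np.isnan(table.areas[0, 0])


class TestSklearnInterface:
    def test_pipeline_composition(self, rng):
        mz = 700 + np.arange(2000) * 0.05
        spectra = [
            Spectrum(mz, _gauss(mz, 712.3777, 50 * (1 + i), 0.1) + 5.0) for i in range(4)
        ]
        pipe = Pipeline(
            [
                ("baseline", ConvexHullBaseline()),
                ("tic", TICNormalizer()),
                ("align", SpectrumAligner(reference_mz=[712.3777], max_shift=0.5)),
                ("bins", PeakBinner(snr_min=3.0, tol=0.3)),
            ]
        )
        areas = pipe.fit_transform(spectra)
        assert areas.shape[0] == 4
        binner = pipe.named_steps["bins"]
        assert any(abs(b.center - 712.3777) < 0.1 for b in binner.bins_)
        # TIC normalization collapses the amplitude differences
        j = int(np.argmin([abs(b.center - 712.3777) for b in binner.bins_]))
        assert np.ptp(areas[:, j]) / areas[:, j].mean() < 0.02

    def test_get_set_params_and_clone(self):
        binner = PeakBinner(snr_min=4.0, tol=0.2)
        assert binner.get_params()["snr_min"] == 4.0
        cloned = clone(binner)
        assert cloned.get_params() == binner.get_params()
        cloned.set_params(tol=0.5)
        assert cloned.tol == 0.5 and binner.tol == 0.2
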