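"""Spectral processing chain for MALDI-TOF imaging spectra.

Stage order mirrors acquisition-software practice and is fixed:

    baseline (convex hull) -> TIC normalization -> m/z alignment
    -> peak detection (S/N > 3) -> cross-spectrum binning -> AUC integration

Each stage exists both as a plain function operating on :class:`Spectrum`
objects and as an sklearn-compatible transformer (``fit``/``transform``,
``get_params``/``set_params``) so the chain composes with
:class:`sklearn.pipeline.Pipeline` over lists of spectra.

Numerical choices: the baseline is the exact lower convex hull of the
(m/z, intensity) point set (Andrew monotone chain — robust on collinear
degenerate inputs where qhull fails); noise for peak detection is a sliding
window median-absolute-deviation scaled by 1.4826 (consistent for Gaussian
noise); alignment fits one rigid m/z shift per spectrum by matched-filter
cross-correlation around reference masses; binning is a greedy sorted
single pass with running-mean centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .model import IMSSection, PeakBinTable, Spectrum

__all__ = [
    "Peak",
    "BinDefinition",
    "baseline_convex_hull",
    "tic_normalize",
    "align_spectra",
    "mad_noise",
    "local_background_noise",
    "detect_peaks",
    "bin_peaks",
    "integrate_areas",
    "ConvexHullBaseline",
    "TICNormalizer",
    "SpectrumAligner",
    "PeakBinner",
    "preprocess_section",
]

MAD_SCALE = 1.4826  # MAD -> sd for Gaussian noise


@dataclass(frozen=True)
class Peak:
    """One detected peak: apex, integration bounds, and S/N."""

    apex_mz: float
    apex_intensity: float
    left_mz: float
    right_mz: float
    snr: float

    def __post_init__(self) -> None:
        if not (self.left_mz <= self.apex_mz <= self.right_mz):
            raise ValueError("integration bounds must bracket the apex")


@dataclass(frozen=True)
class BinDefinition:
    """One cross-spectrum m/z bin."""

    center: float
    half_width: float
    count: int


# ---------------------------------------------------------------- baseline


def _lower_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull vertices (monotone chain)."""
    xs = x.tolist()
    ys = y.tolist()
    hull: list[int] = []
    for i in range(len(xs)):
        xi, yi = xs[i], ys[i]
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            if (xs[k] - xs[j]) * (yi - ys[j]) - (ys[k] - ys[j]) * (xi - xs[j]) <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.array(hull)


def baseline_convex_hull(spectrum: Spectrum) -> Spectrum:
    """Subtract the lower convex hull of the (m/z, intensity) points.

    Output intensities are >= 0 and both endpoints map exactly to zero.
    A constant or linearly ramping spectrum is flattened to all zeros.
    """
    if spectrum.mz.size < 3:
        raise ValueError("baseline correction needs at least 3 points")
    idx = _lower_hull(spectrum.mz, spectrum.intensity)
    baseline = np.interp(spectrum.mz, spectrum.mz[idx], spectrum.intensity[idx])
    corrected = np.clip(spectrum.intensity - baseline, 0.0, None)
    return Spectrum(spectrum.mz.copy(), corrected)


# ------------------------------------------------------------- normalization


def tic_normalize(spectrum: Spectrum, target_tic: float = 1.0) -> Spectrum:
    """Scale one spectrum so its total ion current equals ``target_tic``."""
    if target_tic <= 0:
        raise ValueError("target_tic must be positive")
    tic = spectrum.tic
    if tic <= 0:
        raise ValueError("zero TIC: spot should have been removed by QC")
    return Spectrum(spectrum.mz.copy(), spectrum.intensity * (target_tic / tic))


# ----------------------------------------------------------------- alignment


def _shift_score(spec: Spectrum, refs: np.ndarray, shifts: np.ndarray,
                 template_sd: float = 0.2, window: float = 0.6) -> np.ndarray:
    """Matched-filter score of each candidate rigid shift."""
    grid = np.linspace(-window, window, 61)
    weights = np.exp(-0.5 * (grid / template_sd) ** 2)
    score = np.zeros_like(shifts)
    for r in refs:
        pts = r + grid[None, :] + shifts[:, None]
        vals = np.interp(pts.ravel(), spec.mz, spec.intensity, left=0.0, right=0.0)
        score += vals.reshape(pts.shape) @ weights
    return score


def align_spectra(
    spectra: list[Spectrum],
    reference_mz: list[float] | np.ndarray,
    max_shift: float = 1.0,
    step: float = 0.01,
) -> tuple[list[Spectrum], np.ndarray, list[bool]]:
    """Estimate and apply one rigid m/z shift per spectrum.

    The shift maximizing the cross-correlation of intensity with Gaussian
    templates at the reference masses is found on a ``step``-spaced grid in
    ``[-max_shift, max_shift]`` with parabolic refinement, then applied by
    linear interpolation onto the original axis. The shifted spectrum is
    rescaled to its pre-shift total ion current (a rigid m/z shift must not
    change total counts), which also makes alignment commute exactly with
    TIC normalization.

    Returns ``(aligned, shifts, warnings)``; a warning flag is set when no
    reference mass falls inside a spectrum's range (returned unshifted) or
    when the estimate hits the ``max_shift`` clamp.
    """
    refs = np.asarray(reference_mz, dtype=float)
    if refs.size == 0:
        raise ValueError("reference_mz must be non-empty")
    if max_shift <= 0:
        raise ValueError("max_shift must be positive")
    shifts_grid = np.arange(-max_shift, max_shift + step / 2, step)
    aligned, shifts, warnings = [], [], []
    for spec in spectra:
        in_range = refs[(refs >= spec.mz[0]) & (refs <= spec.mz[-1])]
        if in_range.size == 0:
            aligned.append(spec.copy())
            shifts.append(0.0)
            warnings.append(True)
            continue
        score = _shift_score(spec, in_range, shifts_grid)
        k = int(np.argmax(score))
        clamped = k in (0, shifts_grid.size - 1)
        shift = shifts_grid[k]
        if not clamped:
            # parabolic vertex through the three points around the maximum
            y0, y1, y2 = score[k - 1], score[k], score[k + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                shift = shift + 0.5 * step * (y0 - y2) / denom
        shift = float(np.clip(shift, -max_shift, max_shift))
        new_int = np.clip(np.interp(spec.mz + shift, spec.mz, spec.intensity), 0.0, None)
        total = new_int.sum()
        if total > 0:
            new_int *= spec.intensity.sum() / total
        aligned.append(Spectrum(spec.mz.copy(), new_int))
        shifts.append(shift)
        warnings.append(clamped)
    return aligned, np.array(shifts), warnings


# ------------------------------------------------------------ peak detection


def local_background_noise(intensity: np.ndarray, window: int = 101) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window local background (median) and robust noise level
    (1.4826 x windowed MAD), both per sample."""
    y = np.asarray(intensity, dtype=float)
    w = min(window, y.size)
    if w % 2 == 0:
        w -= 1
    w = max(w, 3)
    med = median_filter(y, size=w, mode="reflect")
    mad = median_filter(np.abs(y - med), size=w, mode="reflect")
    return med, MAD_SCALE * mad


def mad_noise(intensity: np.ndarray, window: int = 101) -> np.ndarray:
    """Sliding-window robust noise level: 1.4826 x windowed MAD."""
    return local_background_noise(intensity, window)[1]


def detect_peaks(
    spectrum: Spectrum, snr_min: float = 3.0, noise_window: int = 101
) -> list[Peak]:
    """Detect local maxima exceeding the S/N threshold.

    The S/N of a candidate apex is its height above the local median
    background divided by the sliding-window MAD noise level (residual
    offsets left by hull baseline subtraction over long noisy stretches
    would otherwise count as signal); apexes are strict local maxima;
    integration bounds sit at the nearest flanking local minima (array ends
    count as minima). A peak at a spot where the local noise estimate is
    exactly zero is kept whenever its background-subtracted height is
    positive (infinite S/N).
    """
    y = spectrum.intensity
    mz = spectrum.mz
    n = y.size
    background, noise = local_background_noise(y, noise_window)
    apexes = np.where((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))[0] + 1
    peaks: list[Peak] = []
    for i in apexes:
        height = y[i] - background[i]
        snr = height / noise[i] if noise[i] > 0 else (np.inf if height > 0 else 0.0)
        if snr <= snr_min:
            continue
        j = int(i)
        while j > 0 and y[j - 1] < y[j]:
            j -= 1
        k = int(i)
        while k < n - 1 and y[k + 1] < y[k]:
            k += 1
        peaks.append(Peak(float(mz[i]), float(y[i]), float(mz[j]), float(mz[k]), float(snr)))
    return peaks


# ----------------------------------------------------------------- binning


def bin_peaks(peaklists: list[list[Peak]], tol: float = 0.3) -> list[BinDefinition]:
    """Pool apex m/z values across spectra into common bins.

    Greedy single pass over the sorted apexes: a new bin opens whenever the
    next apex is more than ``tol`` from the current bin's running mean. Bin
    centers are member means; half-widths are the largest member deviation,
    clipped to half the gap to each neighboring center so intervals never
    overlap. Deterministic for fixed input.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    apexes = np.sort(np.array([p.apex_mz for pl in peaklists for p in pl]))
    if apexes.size == 0:
        return []
    groups: list[list[float]] = [[apexes[0]]]
    total, count = apexes[0], 1
    for a in apexes[1:]:
        if a - total / count > tol:
            groups.append([a])
            total, count = a, 1
        else:
            groups[-1].append(a)
            total += a
            count += 1
    centers = np.array([np.mean(g) for g in groups])
    raw_hw = np.array([max(abs(np.array(g) - c).max(), 0.0) for g, c in zip(groups, centers)])
    hw = raw_hw.copy()
    for i in range(centers.size):
        if i > 0:
            hw[i] = min(hw[i], (centers[i] - centers[i - 1]) / 2)
        if i < centers.size - 1:
            hw[i] = min(hw[i], (centers[i + 1] - centers[i]) / 2)
    return [
        BinDefinition(float(c), float(h), len(g))
        for c, h, g in zip(centers, hw, groups)
    ]


# --------------------------------------------------------------- integration


def _area_in_window(spec: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal AUC of intensity over [lo, hi]; NaN when fully outside."""
    mz, y = spec.mz, spec.intensity
    if hi <= mz[0] or lo >= mz[-1]:
        return float("nan")
    lo_c, hi_c = max(lo, mz[0]), min(hi, mz[-1])
    inside = (mz > lo_c) & (mz < hi_c)
    xs = np.concatenate(([lo_c], mz[inside], [hi_c]))
    ys = np.concatenate(
        ([np.interp(lo_c, mz, y)], y[inside], [np.interp(hi_c, mz, y)])
    )
    return float(max(np.trapezoid(ys, xs), 0.0))


def integrate_areas(
    section: IMSSection,
    bins: list[BinDefinition],
    halfwidth_floor: float = 0.25,
    normalized: bool = False,
    aligned: bool = False,
) -> PeakBinTable:
    """Per-spot, per-bin trapezoidal AUC areas.

    The integration window is ``center ± max(bin half-width,
    halfwidth_floor)`` (floor 0.25 Da: unit-resolution TOF peaks). Windows
    entirely outside a spectrum's m/z range yield NaN (missing, not zero).
    """
    centers = np.array([b.center for b in bins])
    areas = np.full((section.n_spots, centers.size), np.nan)
    for i, spec in enumerate(section.spectra):
        for j, b in enumerate(bins):
            h = max(b.half_width, halfwidth_floor)
            areas[i, j] = _area_in_window(spec, b.center - h, b.center + h)
    return PeakBinTable(
        section_id=section.section_id,
        bin_centers=centers,
        areas=areas,
        coords=section.coords.copy(),
        hemispheres=list(section.hemispheres),
        normalized=normalized,
        aligned=aligned,
    )


# ------------------------------------------------------------- transformers


class ConvexHullBaseline(BaseEstimator, TransformerMixin):
    """Stateless transformer applying convex-hull baseline subtraction."""

    def fit(self, X: list[Spectrum], y=None):
        return self

    def transform(self, X: list[Spectrum]) -> list[Spectrum]:
        return [baseline_convex_hull(s) for s in X]


class TICNormalizer(BaseEstimator, TransformerMixin):
    """TIC normalization; the target TIC is learned in ``fit``.

    With ``target_tic=None`` the target is the mean raw TIC of the fitted
    spectra, keeping normalized intensities on the familiar raw scale.
    """

    def __init__(self, target_tic: float | None = None):
        self.target_tic = target_tic

    def fit(self, X: list[Spectrum], y=None):
        if self.target_tic is not None:
            self.target_tic_ = float(self.target_tic)
        else:
            self.target_tic_ = float(np.mean([s.tic for s in X]))
        return self

    def transform(self, X: list[Spectrum]) -> list[Spectrum]:
        return [tic_normalize(s, self.target_tic_) for s in X]


class SpectrumAligner(BaseEstimator, TransformerMixin):
    """Rigid per-spectrum m/z shift alignment to reference masses.

    With ``reference_mz=None`` the packaged peptide catalog's [M+H]+ values
    serve as references. After ``transform``, ``shifts_`` and ``warnings_``
    hold the per-spectrum estimates and clamp/out-of-range flags.
    """

    def __init__(self, reference_mz=None, max_shift: float = 1.0, step: float = 0.01):
        self.reference_mz = reference_mz
        self.max_shift = max_shift
        self.step = step

    def fit(self, X: list[Spectrum], y=None):
        if self.reference_mz is None:
            from .chem import default_catalog

            self.reference_mz_ = np.array([p.mh for p in default_catalog()])
        else:
            self.reference_mz_ = np.asarray(self.reference_mz, dtype=float)
        return self

    def transform(self, X: list[Spectrum]) -> list[Spectrum]:
        aligned, self.shifts_, self.warnings_ = align_spectra(
            X, self.reference_mz_, max_shift=self.max_shift, step=self.step
        )
        return aligned


class PeakBinner(BaseEstimator, TransformerMixin):
    """Learn common m/z bins from detected peaks; emit per-spectrum areas.

    ``fit`` runs S/N-thresholded peak detection on every spectrum and pools
    the apexes into bins (``bins_``); ``transform`` integrates each
    spectrum's AUC in every bin, returning an ``(n_spectra, n_bins)`` array
    (NaN where a bin lies outside a spectrum's range).
    """

    def __init__(
        self,
        snr_min: float = 3.0,
        tol: float = 0.3,
        halfwidth_floor: float = 0.25,
        noise_window: int = 101,
    ):
        self.snr_min = snr_min
        self.tol = tol
        self.halfwidth_floor = halfwidth_floor
        self.noise_window = noise_window

    def fit(self, X: list[Spectrum], y=None):
        self.peaklists_ = [
            detect_peaks(s, snr_min=self.snr_min, noise_window=self.noise_window)
            for s in X
        ]
        self.bins_ = bin_peaks(self.peaklists_, tol=self.tol)
        return self

    def transform(self, X: list[Spectrum]) -> np.ndarray:
        out = np.full((len(X), len(self.bins_)), np.nan)
        for i, spec in enumerate(X):
            for j, b in enumerate(self.bins_):
                h = max(b.half_width, self.halfwidth_floor)
                out[i, j] = _area_in_window(spec, b.center - h, b.center + h)
        return out


def preprocess_section(
    section: IMSSection,
    reference_mz=None,
    snr_min: float = 3.0,
    bin_tol: float = 0.3,
    halfwidth_floor: float = 0.25,
    noise_window: int = 101,
    max_shift: float = 1.0,
    bins: list[BinDefinition] | None = None,
) -> tuple[PeakBinTable, dict]:
    """Run the full spectral chain on one section.

    When ``bins`` is given (e.g. pooled across sections) the binning stage
    is skipped and areas are integrated in the provided bins. Returns the
    peak-area table and a log dict with per-stage counts.
    """
    base = ConvexHullBaseline().fit_transform(section.spectra)
    norm = TICNormalizer().fit_transform(base)
    aligner = SpectrumAligner(reference_mz=reference_mz, max_shift=max_shift)
    aligned = aligner.fit_transform(norm)
    if bins is None:
        binner = PeakBinner(
            snr_min=snr_min,
            tol=bin_tol,
            halfwidth_floor=halfwidth_floor,
            noise_window=noise_window,
        ).fit(aligned)
        bins = binner.bins_
        n_peaks = sum(len(pl) for pl in binner.peaklists_)
    else:
        n_peaks = -1
    table = integrate_areas(
        section.with_spectra(aligned),
        bins,
        halfwidth_floor=halfwidth_floor,
        normalized=True,
        aligned=True,
    )
    log = {
        "section_id": section.section_id,
        "n_spots": section.n_spots,
        "n_peaks": n_peaks,
        "n_bins": len(bins),
        "n_align_warnings": int(sum(aligner.warnings_)),
    }
    return table, log
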