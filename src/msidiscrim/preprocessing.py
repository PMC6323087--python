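"""Spectral preprocessing: resampling, baseline correction, outlier
screening, alignment and TIC normalization.

The canonical stage order is resample -> baseline -> outlier removal ->
align -> TIC normalize; :func:`preprocess` runs the whole chain and
returns a :class:`PreprocessReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .io_core import SpectraDataset, ValidationError


@dataclass
class PreprocessReport:
    n_input_pixels: int = 0
    outlier_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    tic_before: np.ndarray = field(default_factory=lambda: np.array([]))
    tic_after: np.ndarray = field(default_factory=lambda: np.array([]))
    shift_per_pixel: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    baseline_fraction_removed: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {
            "n_input_pixels": self.n_input_pixels,
            "n_outliers": int(self.outlier_indices.size),
            "outlier_indices": self.outlier_indices.tolist(),
            "shift_bins": self.shift_per_pixel.tolist(),
            "baseline_fraction_removed": self.baseline_fraction_removed.tolist(),
        }


DEFAULT_GRID_STEP = {"peptide": 0.1, "lipid": 0.05}


def resample(dataset: SpectraDataset, grid_step: float) -> SpectraDataset:
    """Linear interpolation of every pixel onto one uniform grid."""
    if grid_step <= 0:
        raise ValidationError("grid_step must be > 0")
    lo, hi = dataset.mass_range
    if grid_step >= hi - lo:
        raise ValidationError("grid_step larger than the mass range")
    n = int(round((hi - lo) / grid_step)) + 1
    axis = lo + grid_step * np.arange(n)
    if dataset.mz_axis.size == axis.size and np.allclose(dataset.mz_axis, axis):
        return dataset
    out = np.empty((dataset.n_pixels, n))
    for p in range(dataset.n_pixels):
        out[p] = np.interp(axis, dataset.mz_axis, dataset.intensities[p], left=0.0, right=0.0)
    from dataclasses import replace

    return replace(dataset, mz_axis=axis, intensities=out)


def estimate_baseline(spectrum: np.ndarray, mz_axis: np.ndarray, window: float) -> np.ndarray:
    """Adaptive baseline: morphological opening (rolling minimum followed by
    rolling maximum, which removes peaks narrower than the window without
    the phase lag of a plain minimum) then rolling-mean smoothing.  The
    window widens in proportion to local m/z (TOF peaks broaden with mass);
    processing is chunked so the window can vary along the axis.
    """
    step = float(mz_axis[1] - mz_axis[0])
    mz_ref = float(mz_axis[0])
    n = spectrum.size
    baseline = np.empty(n)
    chunk = max(256, n // 16)
    pad = int(3 * window / step)
    for start in range(0, n, chunk):
        end = min(n, start + chunk)
        mid_mz = float(mz_axis[(start + end) // 2])
        w_bins = max(3, int(round(window * (mid_mz / mz_ref) / step)))
        a, b = max(0, start - pad), min(n, end + pad)
        seg = spectrum[a:b]
        opened = ndimage.maximum_filter1d(
            ndimage.minimum_filter1d(seg, size=w_bins, mode="nearest"),
            size=w_bins, mode="nearest",
        )
        smooth = ndimage.uniform_filter1d(opened, size=w_bins, mode="nearest")
        baseline[start:end] = smooth[start - a : end - a]
    return np.minimum(baseline, spectrum)


def baseline_correct(
    dataset: SpectraDataset, window: float = 25.0
) -> tuple[SpectraDataset, np.ndarray]:
    """Subtract the adaptive baseline estimate, clipping at zero."""
    if window <= 0:
        raise ValidationError("baseline window must be > 0")
    baselines = np.empty_like(dataset.intensities)
    out = np.empty_like(dataset.intensities)
    for p in range(dataset.n_pixels):
        b = estimate_baseline(dataset.intensities[p], dataset.mz_axis, window)
        baselines[p] = b
        out[p] = np.clip(dataset.intensities[p] - b, 0.0, None)
    return dataset.with_intensities(out), baselines


def flag_outlier_spectra(dataset: SpectraDataset, tail: float = 0.007) -> np.ndarray:
    """Indices of pixels with extreme TIC.

    Realizes a generalized-boxplot criterion for skewed distributions:
    TICs are log-transformed (making the flagging invariant to global
    rescaling), then asymmetric fences are drawn at
    ``median +- k * semi-interquartile range`` with ``k`` calibrated so a
    normal distribution exceeds each fence with probability ``tail``.
    """
    if dataset.n_pixels < 10:
        raise ValidationError("need at least 10 pixels for outlier screening")
    tics = dataset.tic()
    if np.any(tics <= 0):
        raise ValidationError("nonpositive TIC encountered before outlier screening")
    y = np.log(tics)
    q25, q50, q75 = np.quantile(y, [0.25, 0.5, 0.75])
    z75 = stats.norm.ppf(0.75)
    k = (stats.norm.ppf(1 - tail) - z75) / z75
    lo_fence = q25 - k * (q50 - q25)
    hi_fence = q75 + k * (q75 - q50)
    return np.flatnonzero((y < lo_fence) | (y > hi_fence))


def average_spectrum(dataset: SpectraDataset) -> np.ndarray:
    """Per-bin arithmetic mean over pixels."""
    if dataset.n_pixels < 1:
        raise ValidationError("empty dataset")
    return dataset.intensities.mean(axis=0)


def align_to_average(
    dataset: SpectraDataset, max_shift: float = 1.0
) -> tuple[SpectraDataset, np.ndarray]:
    """Shift each spectrum by the integer-bin lag maximizing its
    cross-correlation (computed via FFT) with the cohort average spectrum.
    """
    step = float(dataset.mz_axis[1] - dataset.mz_axis[0])
    if max_shift < step:
        raise ValidationError("max_shift must be at least one grid step")
    lo, hi = dataset.mass_range
    if max_shift > 0.1 * (hi - lo):
        raise ValidationError("max_shift exceeds 10% of the mass range")
    max_bins = int(round(max_shift / step))
    avg = average_spectrum(dataset)
    n = dataset.n_bins
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    favg = np.fft.rfft(avg, nfft)
    shifts = np.zeros(dataset.n_pixels, dtype=int)
    out = np.zeros_like(dataset.intensities)
    lags = np.concatenate([np.arange(0, max_bins + 1), np.arange(-max_bins, 0)])
    for p in range(dataset.n_pixels):
        xc = np.fft.irfft(favg * np.conj(np.fft.rfft(dataset.intensities[p], nfft)), nfft)
        # xc[l] = sum_t avg[t+l] * s[t]; candidate lags wrap negatives to the end
        cand = xc[lags % nfft]
        lag = int(lags[int(np.argmax(cand))])
        shifts[p] = lag
        s = dataset.intensities[p]
        if lag > 0:  # spectrum lags the average: move it right
            out[p, lag:] = s[: n - lag]
        elif lag < 0:
            out[p, :lag] = s[-lag:]
        else:
            out[p] = s
    return dataset.with_intensities(out), shifts


def tic_normalize(dataset: SpectraDataset) -> SpectraDataset:
    """Scale every spectrum so its TIC equals the cohort mean input TIC."""
    tics = dataset.tic()
    if np.any(tics <= 0):
        bad = int(np.flatnonzero(tics <= 0)[0])
        raise ValidationError(f"pixel {bad} has zero TIC; cannot normalize")
    target = float(tics.mean())
    return dataset.with_intensities(dataset.intensities * (target / tics)[:, None])


def preprocess(
    dataset: SpectraDataset,
    grid_step: float | None = None,
    baseline_window: float = 25.0,
    max_shift: float = 1.0,
    skip_baseline: bool = False,
) -> tuple[SpectraDataset, PreprocessReport]:
    """Full chain: resample -> baseline -> outliers -> align -> TIC norm."""
    report = PreprocessReport(n_input_pixels=dataset.n_pixels)
    if grid_step is None:
        grid_step = DEFAULT_GRID_STEP[dataset.domain]
    ds = resample(dataset, grid_step)
    report.tic_before = ds.tic()
    if skip_baseline:
        baselines = np.zeros_like(ds.intensities)
    else:
        ds, baselines = baseline_correct(ds, baseline_window)
    with np.errstate(divide="ignore", invalid="ignore"):
        removed = baselines.sum(axis=1) / report.tic_before
    report.baseline_fraction_removed = np.nan_to_num(removed)
    outliers = flag_outlier_spectra(ds)
    report.outlier_indices = outliers
    keep = np.setdiff1d(np.arange(ds.n_pixels), outliers)
    ds = ds.subset_pixels(keep)
    ds, shifts = align_to_average(ds, max_shift=max(max_shift, grid_step))
    report.shift_per_pixel = shifts
    ds = tic_normalize(ds)
    report.tic_after = ds.tic()
    return ds, report
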