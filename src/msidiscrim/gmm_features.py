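"""Average-spectrum Gaussian mixture modelling and component quantification.

The cohort average spectrum is treated as an intensity-weighted sample over
m/z and decomposed into Gaussian components by EM, run independently inside
each contiguous above-noise region with peak-maxima initialization and a
per-region BIC sweep.  Fitted components are filtered (high variance / low
amplitude), right-skew satellites are merged leftward onto their major
component, and the surviving "molecular components" are quantified in every
pixel by the inner product of the spectrum with the unit-area component
density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .io_core import FeatureTable, SpectraDataset, ValidationError

FILTER_NONE = ""
FILTER_HIGH_VARIANCE = "high_variance"
FILTER_LOW_AMPLITUDE = "low_amplitude"


@dataclass
class GmmModel:
    """Ordered Gaussian mixture over the average spectrum.

    ``weight`` is the share of total signal mass; ``amplitude`` (weight/sd,
    proportional to density height) is the quantity used for filtering and
    dominance tests.  ``merge_map[i] == j`` means component ``i`` has been
    absorbed into component ``j <= i``; unmerged components map to
    themselves.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    filtered_out: np.ndarray = field(default=None)  # type: ignore[assignment]
    merge_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.means) <= 0):
            raise ValidationError("component means must be strictly increasing")
        if np.any(self.sds <= 0):
            raise ValidationError("component SDs must be > 0")
        if self.filtered_out is None:
            self.filtered_out = np.array([FILTER_NONE] * self.means.size, dtype=object)
        else:
            self.filtered_out = np.asarray(self.filtered_out, dtype=object)
        if self.merge_map is None:
            self.merge_map = np.arange(self.means.size)
        else:
            self.merge_map = np.asarray(self.merge_map, dtype=int)
            if np.any(self.merge_map > np.arange(self.means.size)):
                raise ValidationError("merges must go leftward")

    @property
    def n_components(self) -> int:
        return self.means.size

    def amplitudes(self) -> np.ndarray:
        return self.weights / self.sds

    def surviving(self) -> np.ndarray:
        """Indices of components that are unfiltered merge targets."""
        own = self.merge_map == np.arange(self.n_components)
        return np.flatnonzero(own & (self.filtered_out == FILTER_NONE))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "means": self.means.tolist(),
                    "sds": self.sds.tolist(),
                    "weights": self.weights.tolist(),
                    "filtered_out": self.filtered_out.tolist(),
                    "merge_map": self.merge_map.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GmmModel":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["means"]), np.array(d["sds"]), np.array(d["weights"]),
            np.array(d["filtered_out"], dtype=object), np.array(d["merge_map"]),
        )


# ---------------------------------------------------------------------------
# EM on one contiguous signal region
# ---------------------------------------------------------------------------


def _weighted_em(
    x: np.ndarray,
    w: np.ndarray,
    mu0: np.ndarray,
    sd0: np.ndarray,
    pi0: np.ndarray,
    n_iter: int = 120,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """EM for a 1-D Gaussian mixture with per-point nonnegative weights.

    Returns (means, sds, mixing weights, weighted log-likelihood)."""
    mu, sd, pi = mu0.copy(), sd0.copy(), pi0.copy()
    w_sum = w.sum()
    sd_floor = max(1e-6, (x[1] - x[0]) * 0.25 if x.size > 1 else 1e-6)
    prev_ll = -np.inf
    for _ in range(n_iter):
        # E step
        dens = pi[None, :] * _normal_pdf(x[:, None], mu[None, :], sd[None, :])
        total = dens.sum(axis=1)
        total = np.where(total <= 0, np.finfo(float).tiny, total)
        resp = dens / total[:, None]
        ll = float(np.sum(w * np.log(total)))
        # M step
        rk = (w[:, None] * resp).sum(axis=0)
        rk = np.where(rk <= 0, np.finfo(float).tiny, rk)
        mu = (w[:, None] * resp * x[:, None]).sum(axis=0) / rk
        var = (w[:, None] * resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / rk
        sd = np.sqrt(np.maximum(var, sd_floor**2))
        pi = rk / w_sum
        if abs(ll - prev_ll) < tol * (abs(prev_ll) + 1.0):
            prev_ll = ll
            break
        prev_ll = ll
    return mu, sd, pi, prev_ll


def _normal_pdf(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def _fit_region(
    x: np.ndarray, w: np.ndarray, max_components: int, step: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BIC sweep around the detected-peak count for one signal region."""
    n_eff = w.sum()
    peaks, props = signal.find_peaks(w, prominence=0.02 * w.max())
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(w))])
    order = np.argsort(-w[peaks])
    k_peaks = min(peaks.size, max_components)
    best = None
    k_lo = max(1, k_peaks)
    k_hi = min(max_components, k_peaks + 2, x.size)
    for k in range(k_lo, k_hi + 1):
        if k <= k_peaks:
            mu0 = np.sort(x[peaks[order[:k]]])
        else:
            extra = np.quantile(x, np.linspace(0.1, 0.9, k - k_peaks))
            mu0 = np.sort(np.concatenate([x[peaks], extra]))
        sd0 = np.full(k, max(2 * step, (x[-1] - x[0]) / (4 * k)))
        pi0 = np.full(k, 1.0 / k)
        mu, sd, pi, ll = _weighted_em(x, w, mu0, sd0, pi0)
        bic = -2.0 * ll + (3 * k - 1) * np.log(max(n_eff, 2.0))
        if best is None or bic < best[0]:
            best = (bic, mu, sd, pi)
    _, mu, sd, pi = best
    order = np.argsort(mu)
    return mu[order], sd[order], pi[order]


def fit_gmm(
    avg: np.ndarray,
    mz_axis: np.ndarray,
    max_components: int = 4000,
    seed: int = 0,
    noise_level: float | None = None,
    min_region_bins: int = 3,
) -> GmmModel:
    """Decompose the average spectrum into Gaussian components.

    The axis is split at runs of near-zero signal (below ``noise_level``,
    default 0.1% of the spectrum maximum); EM with a BIC sweep runs per
    region.  Deterministic: initialization is from detected peak maxima,
    no random restarts are needed.
    """
    avg = np.asarray(avg, dtype=float)
    mz_axis = np.asarray(mz_axis, dtype=float)
    if avg.size != mz_axis.size:
        raise ValidationError("average spectrum and m/z axis length mismatch")
    if not np.any(avg > 0):
        raise ValidationError("all-zero average spectrum")
    if noise_level is None:
        noise_level = 1e-3 * float(avg.max())
    step = float(mz_axis[1] - mz_axis[0])
    above = avg > noise_level
    # close 1-bin gaps so a single peak is not split by one noisy bin
    above = above | np.roll(above, 1) & np.roll(above, -1)
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] if above[0] else []
    regions: list[tuple[int, int]] = []
    for e in edges:
        if above[e + 1]:
            starts.append(e + 1)
        else:
            regions.append((starts.pop(), e + 1))
    if starts:
        regions.append((starts.pop(), avg.size))

    means, sds, weights = [], [], []
    total_mass = float((avg * step).sum())
    budget = max_components
    for a, b in regions:
        if b - a < min_region_bins or budget <= 0:
            continue
        x, w = mz_axis[a:b], avg[a:b] - noise_level
        w = np.clip(w, 0.0, None)
        if w.sum() <= 0:
            continue
        region_mass = float((avg[a:b] * step).sum())
        k_max = min(budget, max(1, (b - a) // min_region_bins))
        mu, sd, pi = _fit_region(x, w, k_max, step)
        budget -= mu.size
        means.extend(mu)
        sds.extend(sd)
        weights.extend(pi * region_mass / total_mass)
    if not means:
        raise ValidationError("no signal regions found above noise level")
    means = np.array(means)
    order = np.argsort(means)
    means = means[order]
    # enforce strict ordering against numerically coincident means
    for i in range(1, means.size):
        if means[i] <= means[i - 1]:
            means[i] = means[i - 1] + 1e-9
    return GmmModel(means, np.array(sds)[order], np.array(weights)[order])


# ---------------------------------------------------------------------------
# filtering, merging, quantification
# ---------------------------------------------------------------------------


def filter_components(
    model: GmmModel, sd_max: float, weight_min: float
) -> GmmModel:
    """Annotate components with high variance or low amplitude.

    Flags are annotations only — nothing is deleted.  ``weight_min`` is a
    fraction of the maximum amplitude (density height) in the model.
    """
    if sd_max <= 0 or weight_min < 0:
        raise ValidationError("thresholds must be positive")
    flags = np.array([FILTER_NONE] * model.n_components, dtype=object)
    amp = model.amplitudes()
    amp_floor = weight_min * amp.max()
    flags[amp < amp_floor] = FILTER_LOW_AMPLITUDE
    flags[model.sds > sd_max] = FILTER_HIGH_VARIANCE
    return GmmModel(
        model.means.copy(), model.sds.copy(), model.weights.copy(),
        flags, model.merge_map.copy(),
    )


def merge_skewed(
    model: GmmModel, envelope_window: float = 3.1, dominance_ratio: float = 0.9
) -> GmmModel:
    """Merge right-skew satellites onto their left-neighbouring major peak.

    A component is a satellite when a larger-amplitude, unfiltered component
    lies within ``envelope_window`` to its left and its own amplitude is
    strictly below ``dominance_ratio`` times that neighbour's.  Satellites
    chain transitively (always leftward) onto the ultimate major component.
    """
    n = model.n_components
    amp = model.amplitudes()
    merge_map = np.arange(n)
    ok = model.filtered_out == FILTER_NONE
    for i in range(1, n):
        if not ok[i]:
            continue
        # candidate majors strictly left within the window
        best_j, best_amp = -1, amp[i]
        for j in range(i - 1, -1, -1):
            if model.means[i] - model.means[j] > envelope_window:
                break
            if not ok[j]:
                continue
            if amp[j] > best_amp and amp[i] < dominance_ratio * amp[j]:
                best_j, best_amp = j, amp[j]
        if best_j >= 0:
            merge_map[i] = merge_map[best_j]  # transitive leftward chaining
    return GmmModel(
        model.means.copy(), model.sds.copy(), model.weights.copy(),
        model.filtered_out.copy(), merge_map,
    )


def quantify_abundances(model: GmmModel, dataset: SpectraDataset) -> FeatureTable:
    """Abundance(c, p) = sum_bins spectrum_p * phi_c * step.

    ``phi_c`` is the weight-combined unit-area density of surviving
    component ``c`` plus any satellites merged into it."""
    surv = model.surviving()
    if surv.size == 0:
        raise ValidationError("no surviving components to quantify")
    step = float(dataset.mz_axis[1] - dataset.mz_axis[0])
    mz = dataset.mz_axis
    densities = np.zeros((surv.size, mz.size))
    for row, c in enumerate(surv):
        members = np.flatnonzero(
            (model.merge_map == c) & (model.filtered_out == FILTER_NONE)
        )
        wsum = model.weights[members].sum()
        for m in members:
            frac = model.weights[m] / wsum if wsum > 0 else 1.0 / members.size
            lo = np.searchsorted(mz, model.means[m] - 6 * model.sds[m])
            hi = np.searchsorted(mz, model.means[m] + 6 * model.sds[m])
            densities[row, lo:hi] += frac * _normal_pdf(
                mz[lo:hi], model.means[m], model.sds[m]
            )
    abundances = dataset.intensities @ densities.T * step
    return FeatureTable(
        model.means[surv], abundances.T, domain=dataset.domain
    )


def extract_features(
    dataset: SpectraDataset,
    max_components: int = 4000,
    sd_max: float | None = None,
    weight_min: float = 0.01,
    envelope_window: float = 3.1,
    dominance_ratio: float = 0.9,
    seed: int = 0,
) -> tuple[FeatureTable, GmmModel]:
    """Full chain on a preprocessed dataset: fit -> filter -> merge -> quantify."""
    from .preprocessing import average_spectrum

    avg = average_spectrum(dataset)
    model = fit_gmm(avg, dataset.mz_axis, max_components=max_components, seed=seed)
    if sd_max is None:
        sd_max = 5.0 * float(np.median(model.sds))
    model = filter_components(model, sd_max=sd_max, weight_min=weight_min)
    model = merge_skewed(model, envelope_window, dominance_ratio)
    return quantify_abundances(model, dataset), model
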