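"""Phantom MSI generator with planted ground truth.

Builds labelled tissue images (cancer blob + epithelium band on a raster),
a library of Gaussian molecular components with controllable between-region
effect sizes and optional right-side isotope-like satellites, and renders
per-pixel spectra with baseline drift, m/z jitter, TIC variation and
outlier pixels.  Every planted quantity is recorded so downstream stages
can be audited against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .io_core import FeatureTable, RoiMask, SpectraDataset, ValidationError

ISOTOPE_SPACING_DA = 1.003  # right-side satellite spacing (singly charged)


@dataclass(frozen=True)
class ComponentTruth:
    """One planted molecular component."""

    mz: float  # true centre, Da
    sd: float  # peak SD, Da
    satellite_offsets: tuple[float, ...]  # right-shifted only, Da
    satellite_weights: tuple[float, ...]  # relative to main peak
    mean_epithelium: float
    mean_cancer: float
    cv_epithelium: float
    cv_cancer: float
    target_d: float  # planted robust effect size (0 = not discriminatory)

    @property
    def discriminatory(self) -> bool:
        return self.target_d != 0.0


@dataclass(frozen=True)
class PhantomTruth:
    """Everything planted into a synthetic dataset."""

    region_map: np.ndarray  # (ny, nx) of {"cancer","epithelium","background"}
    components: tuple[ComponentTruth, ...]
    outlier_pixels: frozenset[int] = frozenset()
    shape: tuple[int, int] = (0, 0)
    mass_range: tuple[float, float] = (800.0, 4000.0)
    seed: int = 0
    params: dict = field(default_factory=dict)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# region map
# ---------------------------------------------------------------------------


def make_phantom(shape: tuple[int, int], cancer_fraction: float, seed: int) -> np.ndarray:
    """Region map with a connected cancer blob inside an epithelium field.

    All grid pixels are tissue (epithelium unless claimed by the blob); the
    cancer blob grows from a seeded centre by randomized breadth-first
    accretion until its share of tissue pixels reaches ``cancer_fraction``
    (guaranteed within +-5% by exact pixel-count targeting).
    """
    ny, nx = shape
    if ny < 2 or nx < 2:
        raise ValidationError(f"degenerate grid shape {shape}")
    if not 0.0 < cancer_fraction < 1.0:
        raise ValidationError("cancer_fraction must be in (0, 1)")
    rng = _rng(seed)
    n_tissue = ny * nx
    target = int(round(cancer_fraction * n_tissue))
    target = max(1, min(n_tissue - 1, target))
    region = np.full((ny, nx), "epithelium", dtype=object)
    cy = int(rng.integers(ny // 4, max(ny // 4 + 1, 3 * ny // 4)))
    cx = int(rng.integers(nx // 4, max(nx // 4 + 1, 3 * nx // 4)))
    blob = {(cy, cx)}
    frontier = [(cy, cx)]
    while len(blob) < target and frontier:
        idx = int(rng.integers(len(frontier)))
        y, x = frontier[idx]
        neigh = [
            (y + dy, x + dx)
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= y + dy < ny and 0 <= x + dx < nx and (y + dy, x + dx) not in blob
        ]
        if not neigh:
            frontier.pop(idx)
            continue
        pick = neigh[int(rng.integers(len(neigh)))]
        blob.add(pick)
        frontier.append(pick)
    for y, x in blob:
        region[y, x] = "cancer"
    return region


# ---------------------------------------------------------------------------
# component library
# ---------------------------------------------------------------------------


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _trimmed_winsor_moments(sigma: float, trim: float = 0.2) -> tuple[float, float]:
    """Population 20%-trimmed mean and Winsorized SD of LogNormal(0, sigma)."""
    dist = stats.lognorm(s=sigma)
    lo, hi = dist.ppf(trim), dist.ppf(1 - trim)
    tm = dist.expect(lambda x: x, lb=lo, ub=hi) / (1 - 2 * trim)
    ew = dist.expect(lambda x: np.clip(x, lo, hi))
    ew2 = dist.expect(lambda x: np.clip(x, lo, hi) ** 2)
    return tm, float(np.sqrt(ew2 - ew * ew))


def solve_mean_shift(target_d: float, cv: float, trim: float = 0.2) -> float:
    """Multiplier applied to the cancer-region mean so the population robust
    effect size (trimmed-mean difference over pooled Winsorized SD) equals
    ``target_d``.

    Scaling LogNormal(mu, sigma) by ``e**delta`` scales both the trimmed mean
    and the Winsorized SD, so the effect size has a closed form in ``delta``
    solved by bracketed root finding.
    """
    if target_d == 0:
        return 1.0
    sigma = _lognormal_sigma(cv)
    tm0, sw0 = _trimmed_winsor_moments(sigma, trim)

    def f(delta: float) -> float:
        s = np.exp(delta)
        pooled = sw0 * np.sqrt((s * s + 1.0) / 2.0)
        return (s - 1.0) * tm0 / pooled - target_d

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 64:
            raise ValidationError(f"cannot reach effect size {target_d}")
    delta = optimize.brentq(f, 0.0, hi, xtol=1e-12)
    return float(np.exp(delta))


def make_component_library(
    n_components: int,
    mass_range: tuple[float, float],
    frac_discriminatory: float = 0.3,
    effect_size_range: tuple[float, float] = (0.5, 2.0),
    skew_fraction: float = 0.2,
    seed: int = 0,
    peak_sd: float = 0.25,
    base_cv: float = 0.2,
    trim: float = 0.2,
    min_separation: float | None = None,
) -> tuple[ComponentTruth, ...]:
    """Sample a library of planted components.

    Centres are drawn without collision (minimum separation 4 peak SDs);
    a ``frac_discriminatory`` share receives cancer-vs-epithelium mean
    shifts solved to hit a robust Cohen's d drawn from
    ``effect_size_range``; a ``skew_fraction`` share carries 1-3 right-side
    satellites at ~1.003 Da spacing with decaying weights.
    """
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    lo, hi = mass_range
    if hi <= lo:
        raise ValidationError("empty mass range")
    rng = _rng(seed)
    min_sep = min_separation if min_separation is not None else 4.0 * peak_sd
    if min_sep < 4.0 * peak_sd:
        raise ValidationError("min_separation must be >= 4 peak SDs")
    # satellites extend ~3 Da right of the centre; keep everything in range
    usable_lo, usable_hi = lo + 4 * peak_sd, hi - 4.0 - 4 * peak_sd
    if (usable_hi - usable_lo) < n_components * min_sep * 1.5:
        raise ValidationError(
            "mass range too dense for requested component count; "
            "reduce n_components or peak_sd"
        )
    centres: list[float] = []
    attempts = 0
    while len(centres) < n_components:
        attempts += 1
        if attempts > 200 * n_components:
            raise ValidationError(
                "could not place components at the required separation; "
                "reduce n_components"
            )
        c = float(rng.uniform(usable_lo, usable_hi))
        if all(abs(c - c0) >= min_sep for c0 in centres):
            centres.append(c)
    centres.sort()

    n_disc = int(round(frac_discriminatory * n_components))
    disc_idx = set(rng.choice(n_components, size=n_disc, replace=False).tolist())
    n_skew = int(round(skew_fraction * n_components))
    skew_idx = set(rng.choice(n_components, size=n_skew, replace=False).tolist())

    comps: list[ComponentTruth] = []
    for i, c in enumerate(centres):
        base_mean = float(rng.uniform(50.0, 500.0))
        cv_e = base_cv * float(rng.uniform(0.8, 1.2))
        cv_c = base_cv * float(rng.uniform(0.8, 1.2))
        if i in disc_idx:
            d = float(rng.uniform(*effect_size_range))
            shift = solve_mean_shift(d, 0.5 * (cv_e + cv_c), trim)
        else:
            d, shift = 0.0, 1.0
        if i in skew_idx:
            n_sat = int(rng.integers(1, 4))
            offsets = tuple(ISOTOPE_SPACING_DA * k for k in range(1, n_sat + 1))
            w0 = float(rng.uniform(0.35, 0.6))
            weights = tuple(w0**k for k in range(1, n_sat + 1))
        else:
            offsets, weights = (), ()
        comps.append(
            ComponentTruth(
                mz=c,
                sd=peak_sd,
                satellite_offsets=offsets,
                satellite_weights=weights,
                mean_epithelium=base_mean,
                mean_cancer=base_mean * shift,
                cv_epithelium=cv_e,
                cv_cancer=cv_c,
                target_d=d,
            )
        )
    return tuple(comps)


# ---------------------------------------------------------------------------
# abundance sampling (shared by spectrum rendering and the fast table path)
# ---------------------------------------------------------------------------


def _sample_abundances(
    components: tuple[ComponentTruth, ...],
    region_flat: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_components, n_pixels) log-normal abundances around region means."""
    n_px = region_flat.size
    out = np.zeros((len(components), n_px))
    is_cancer = region_flat == "cancer"
    for ci, comp in enumerate(components):
        for mask, mean, cv in (
            (is_cancer, comp.mean_cancer, comp.cv_cancer),
            (~is_cancer, comp.mean_epithelium, comp.cv_epithelium),
        ):
            n = int(mask.sum())
            if n == 0:
                continue
            sigma = _lognormal_sigma(cv)
            mu = np.log(mean) - 0.5 * sigma * sigma  # E[lognormal] = mean
            out[ci, mask] = rng.lognormal(mu, sigma, size=n)
    return out


def make_abundance_table(
    region_map: np.ndarray,
    components: tuple[ComponentTruth, ...],
    seed: int,
    domain: str = "peptide",
) -> tuple[FeatureTable, RoiMask, np.ndarray]:
    """Directly sampled component-by-pixel abundances (no spectra).

    Fast path for exercising statistics, segmentation and classification
    without rendering and re-quantifying full spectra.  Returns the table,
    a matching ROI mask and the row-major pixel coordinates.
    """
    rng = _rng(seed)
    ny, nx = region_map.shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    region_flat = region_map.ravel()
    keep = region_flat != "background"
    coords = coords[keep]
    region_flat = region_flat[keep]
    ab = _sample_abundances(components, region_flat, rng)
    labels = np.where(region_flat == "cancer", "cancer", "epithelium").astype(object)
    table = FeatureTable(
        np.array([c.mz for c in components]), ab, domain=domain
    )
    return table, RoiMask(labels), coords


# ---------------------------------------------------------------------------
# spectrum rendering
# ---------------------------------------------------------------------------


def synthesize_dataset(
    region_map: np.ndarray,
    components: tuple[ComponentTruth, ...],
    noise_sd: float = 0.0,
    baseline_amp: float = 0.0,
    mz_jitter_sd: float = 0.0,
    tic_spread: float = 0.0,
    outlier_rate: float = 0.0,
    seed: int = 0,
    grid_step: float = 0.1,
    mass_range: tuple[float, float] = (800.0, 4000.0),
    domain: str = "peptide",
    specimen_id: str = "phantom",
) -> tuple[SpectraDataset, RoiMask, PhantomTruth]:
    """Render per-pixel spectra from planted truth.

    Each spectrum is the sum of Gaussian peaks (centres jittered per pixel,
    abundances log-normal around the pixel's region mean, satellites scaled
    to the main peak), plus a smooth low-frequency baseline and nonnegative
    noise, all multiplied by a per-pixel TIC factor.  ``outlier_rate``
    pixels get their TIC multiplied by >=10 or <=0.1.
    """
    for name, r in (("noise_sd", noise_sd), ("baseline_amp", baseline_amp),
                    ("tic_spread", tic_spread), ("outlier_rate", outlier_rate)):
        if not 0.0 <= r < 1.0:
            raise ValidationError(f"{name} must be in [0, 1)")
    rng = _rng(seed)
    ny, nx = region_map.shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    region_flat = region_map.ravel()
    keep = region_flat != "background"
    coords = coords[keep]
    region_flat = region_flat[keep]
    n_px = coords.shape[0]

    lo, hi = mass_range
    axis = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    n_bins = axis.size

    abund = _sample_abundances(components, region_flat, rng)
    jitter = (
        rng.normal(0.0, mz_jitter_sd, size=n_px) if mz_jitter_sd > 0 else np.zeros(n_px)
    )
    if tic_spread > 0:
        tic_factor = rng.lognormal(0.0, _lognormal_sigma(tic_spread), size=n_px)
    else:
        tic_factor = np.ones(n_px)
    out_mask = rng.random(n_px) < outlier_rate
    big = rng.random(out_mask.sum()) < 0.5
    sev = np.where(big, rng.uniform(10.0, 20.0, big.size), rng.uniform(0.02, 0.1, big.size))
    tic_factor[out_mask] *= sev
    outlier_pixels = frozenset(np.flatnonzero(out_mask).tolist())

    ref_scale = float(np.mean([c.mean_epithelium for c in components])) if components else 1.0
    spectra = np.zeros((n_px, n_bins))
    window = 5.0  # Da rendered around each peak centre
    for p in range(n_px):
        s = spectra[p]
        dj = jitter[p]
        for ci, comp in enumerate(components):
            a = abund[ci, p]
            if a <= 0:
                continue
            for off, w in zip((0.0, *comp.satellite_offsets), (1.0, *comp.satellite_weights)):
                centre = comp.mz + off + dj
                i0 = np.searchsorted(axis, centre - window)
                i1 = np.searchsorted(axis, centre + window)
                if i1 <= i0:
                    continue
                x = axis[i0:i1]
                s[i0:i1] += (
                    a * w / (comp.sd * np.sqrt(2 * np.pi))
                    * np.exp(-0.5 * ((x - centre) / comp.sd) ** 2)
                )
        if baseline_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            t = np.linspace(0, 1, n_bins)
            base = (
                baseline_amp * ref_scale
                * (1.2 + np.sin(2 * np.pi * (1.0 + 0.5 * rng.random()) * t + phase))
                * np.exp(-2.0 * t)
            )
            s += np.clip(base, 0, None)
        if noise_sd > 0:
            s += np.abs(rng.normal(0.0, noise_sd * ref_scale, size=n_bins))
        s *= tic_factor[p]

    labels = np.where(region_flat == "cancer", "cancer", "epithelium").astype(object)
    dataset = SpectraDataset(
        axis, spectra, coords,
        specimen_id=specimen_id, domain=domain, mass_range=mass_range,
    )
    truth = PhantomTruth(
        region_map=region_map,
        components=components,
        outlier_pixels=outlier_pixels,
        shape=(ny, nx),
        mass_range=mass_range,
        seed=seed,
        params=dict(
            noise_sd=noise_sd, baseline_amp=baseline_amp,
            mz_jitter_sd=mz_jitter_sd, tic_spread=tic_spread,
            outlier_rate=outlier_rate, grid_step=grid_step,
        ),
    )
    return dataset, RoiMask(labels), truth
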