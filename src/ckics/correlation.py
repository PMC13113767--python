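"""k-space image correlation: FFT, temporal correlation, circular averaging.

The kICS correlation function of an image series I(x, t) is

    r(k, τ) = ⟨ Ĩ(k, t) · Ĩ*(k, t + τ) ⟩_t ,

with Ĩ the 2D spatial Fourier transform of each (mean-subtracted) frame.  For
an isotropic system r depends on k only through k² = |k|², so the raw CF is
averaged over annuli in |k| and reported against the mean k² of each
annulus.  Wavenumbers use the angular convention k = 2π·f (f in cycles/μm),
which puts the k² axis on the 0–200 μm⁻² scale familiar from membrane
imaging at 0.1 μm pixels.

Normalizing each k² bin by its τ = 0 value cancels all static prefactors
(PSF envelope, particle number, quantum yield): a single freely diffusing
species then leaves exactly exp(−k²·D·τ).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .imaging import ImageSeries

__all__ = [
    "KSpaceSeries",
    "KICSCorrelation",
    "spatial_transform",
    "temporal_correlation",
    "circular_average",
    "normalize_cf",
    "compute_kics_cf",
]

logger = logging.getLogger("ckics")

DEFAULT_MAX_TAU = 100  # frames; CF estimates at longer lags are noise-dominated
IMAG_WARN_FRACTION = 0.05  # |Im|/|Re| above this hints at non-stationarity


@dataclass
class KSpaceSeries:
    """Per-frame 2D Fourier transforms with their wavevector grids."""

    kframes: np.ndarray  # (T, H, W) complex
    kx: np.ndarray  # (W,) μm⁻¹, angular
    ky: np.ndarray  # (H,) μm⁻¹, angular
    pixel_size: float
    frame_time: float

    @property
    def k2_grid(self) -> np.ndarray:
        return self.ky[:, None] ** 2 + self.kx[None, :] ** 2


@dataclass
class KICSCorrelation:
    """Circularly averaged correlation surface r(k², τ).

    ``values`` has shape (n_tau, n_k2); ``mask`` marks k² bins usable for
    fitting (True = keep).  ``imag_fraction`` is the relative magnitude of
    the imaginary residue of the raw CF, a stationarity diagnostic.
    """

    k2_grid: np.ndarray  # μm⁻², strictly increasing bin centers
    tau_grid: np.ndarray  # s, starting at 0
    values: np.ndarray  # (n_tau, n_k2)
    n_pairs: np.ndarray  # frame pairs averaged per τ
    pixel_size: float
    normalized: bool = False
    mask: np.ndarray | None = None
    imag_fraction: float = 0.0
    omega0_hint: float | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(len(self.k2_grid), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (k², τ) with the pair count."""
        n_tau, n_k2 = self.values.shape
        return pd.DataFrame(
            {
                "k2": np.tile(self.k2_grid, n_tau),
                "tau": np.repeat(self.tau_grid, n_k2),
                "value": self.values.ravel(),
                "n_pairs": np.repeat(self.n_pairs, n_k2),
            }
        )


def spatial_transform(series: ImageSeries, subtract_mean: bool = True) -> KSpaceSeries:
    """2D FFT of every frame; by default the per-frame spatial mean is removed.

    Mean subtraction kills the DC term so a uniform immobile background does
    not dominate the correlation.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames for a temporal correlation")
    frames = series.frames.astype(np.float64, copy=False)
    if subtract_mean:
        frames = frames - frames.mean(axis=(1, 2), keepdims=True)
    kframes = np.fft.fft2(frames).astype(np.complex64)
    H, W = series.frame_shape
    kx = 2.0 * np.pi * np.fft.fftfreq(W, d=series.pixel_size)
    ky = 2.0 * np.pi * np.fft.fftfreq(H, d=series.pixel_size)
    return KSpaceSeries(kframes, kx, ky, series.pixel_size, series.frame_time)


def temporal_correlation(kspace: KSpaceSeries, max_tau: int = DEFAULT_MAX_TAU) -> np.ndarray:
    """Raw per-mode CF r(k, τ) for τ = 0..max_tau, complex, shape (τ, H, W).

    Each lag averages all n_frames − τ frame pairs.
    """
    T = kspace.kframes.shape[0]
    if max_tau >= T:
        raise ValueError(f"max_tau ({max_tau}) must be < number of frames ({T})")
    kf = kspace.kframes
    out = np.empty((max_tau + 1,) + kf.shape[1:], dtype=np.complex128)
    for tau in range(max_tau + 1):
        a = kf[: T - tau]
        b = kf[tau:]
        out[tau] = np.einsum("tij,tij->ij", a, np.conj(b)) / (T - tau)
    return out


def circular_average(
    raw_cf: np.ndarray, kspace: KSpaceSeries
) -> KICSCorrelation:
    """Average the raw CF over annuli of one frequency step in |k|.

    Bin b collects the modes with round(|k|/Δk) = b, Δk = 2π/(N·pixel_size);
    the DC mode is excluded and bins run to the Nyquist ring (N/2 bins for
    even N).  Bin centers are the mean k² of the member modes, which avoids
    the small-k bias of nominal ring radii.
    """
    H, W = kspace.kframes.shape[1:]
    if H != W:
        raise ValueError("circular averaging expects square frames")
    N = H
    dk = 2.0 * np.pi / (N * kspace.pixel_size)
    k2 = kspace.k2_grid
    ring = np.rint(np.sqrt(k2) / dk).astype(np.int64).ravel()
    n_bins = N // 2
    valid = (ring >= 1) & (ring <= n_bins)
    ring_v = ring[valid]

    counts = np.bincount(ring_v, minlength=n_bins + 1)[1:]
    k2_sum = np.bincount(ring_v, weights=k2.ravel()[valid], minlength=n_bins + 1)[1:]
    k2_centers = k2_sum / counts

    n_tau = raw_cf.shape[0]
    values = np.empty((n_tau, n_bins))
    imag_norm = 0.0
    real_norm = 0.0
    for t in range(n_tau):
        flat = raw_cf[t].ravel()[valid]
        re = np.bincount(ring_v, weights=flat.real, minlength=n_bins + 1)[1:]
        im = np.bincount(ring_v, weights=flat.imag, minlength=n_bins + 1)[1:]
        values[t] = re / counts
        real_norm += float(np.sum((re / counts) ** 2))
        imag_norm += float(np.sum((im / counts) ** 2))

    imag_fraction = float(np.sqrt(imag_norm / real_norm)) if real_norm > 0 else 0.0
    if imag_fraction > IMAG_WARN_FRACTION:
        logger.warning(
            "imaginary CF residue %.3f of the real part — series may be "
            "non-stationary",
            imag_fraction,
        )

    T = kspace.kframes.shape[0]
    n_pairs = T - np.arange(n_tau)
    tau_grid = np.arange(n_tau) * kspace.frame_time
    return KICSCorrelation(
        k2_grid=k2_centers,
        tau_grid=tau_grid,
        values=values,
        n_pairs=n_pairs,
        pixel_size=kspace.pixel_size,
        normalized=False,
        imag_fraction=imag_fraction,
    )


def normalize_cf(cf: KICSCorrelation, rel_floor: float = 1e-9) -> KICSCorrelation:
    """Divide each k² bin by its τ = 0 value.

    Bins whose τ = 0 power is non-positive or below ``rel_floor`` times the
    maximum are masked out rather than producing unstable ratios.
    """
    if cf.normalized:
        return cf
    r0 = cf.values[0]
    floor = rel_floor * float(np.max(np.abs(r0))) if r0.size else 0.0
    good = r0 > floor
    n_bad = int(np.sum(~good))
    if n_bad:
        logger.warning("masking %d k² bins with near-zero τ=0 power", n_bad)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.where(good[None, :], cf.values / np.where(good, r0, 1.0), np.nan)
    return replace(
        cf,
        values=values,
        normalized=True,
        mask=(cf.mask & good) if cf.mask is not None else good,
    )


def compute_kics_cf(
    series: ImageSeries,
    max_tau: int = DEFAULT_MAX_TAU,
    subtract_mean: bool = True,
    normalize: bool = False,
) -> KICSCorrelation:
    """Full CF pipeline: FFT → temporal correlation → circular average."""
    kspace = spatial_transform(series, subtract_mean=subtract_mean)
    max_tau = min(max_tau, series.n_frames - 1)
    raw = temporal_correlation(kspace, max_tau)
    cf = circular_average(raw, kspace)
    cf.omega0_hint = series.psf_radius
    return normalize_cf(cf) if normalize else cf
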