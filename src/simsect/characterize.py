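"""System-characterization analytics.

Everything needed to pick an operating grid frequency from acquired (or
simulated) phase triplets: per-pixel modulation depth, the uniform/
sectioned SNR trade-off, axial profiles and measured section thickness,
target contrast ratio, and FFT frequency calibration.

Modulation depth estimator (per pixel): the sectioned image recovers
the AC amplitude B of the three-point cosine and the widefield image its
DC level A, so m(x, y) = I_sectioned / I_widefield.

SNR of the two reconstructions, for per-frame noise std sigma: the
widefield average has noise sigma/sqrt(3) and first-order propagation
through the square law gives sectioned noise sigma*sqrt(2/3), so

    SNR_uniform   = sqrt(3)   * mean(I_W) / sigma
    SNR_sectioned = sqrt(3/2) * m * mean(I_W) / sigma
    ratio         = SNR_uniform / SNR_sectioned = sqrt(2) / m

— the SNR penalty of sectioning depends only on the measured modulation
depth, not on how (frequency or turbidity) that depth arose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .optics import GridFrequency, OpticalConfig, normalized_frequency
from .reconstruct import sectioned_image, widefield_image
from .simulate import NoiseModel, PhaseTriplet

__all__ = [
    "Roi",
    "ModulationMap",
    "AxialProfile",
    "SnrReport",
    "FrequencyEstimate",
    "ContrastReport",
    "modulation_map",
    "snr_report",
    "axial_profile",
    "section_thickness_from_profile",
    "section_thickness_subrois",
    "contrast_ratio",
    "estimate_frequency",
]


@dataclass(frozen=True)
class Roi:
    """Half-open pixel rectangle [row0, row1) x [col0, col1), origin top-left."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("ROI must have positive extent")

    def check_inside(self, shape) -> None:
        if self.row0 < 0 or self.col0 < 0 or self.row1 > shape[0] or self.col1 > shape[1]:
            raise ValueError(f"ROI {self} outside image of shape {shape}")

    def slice(self):
        return (slice(self.row0, self.row1), slice(self.col0, self.col1))

    @property
    def n_pixels(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    def area_mm2(self, config: OpticalConfig) -> float:
        return self.n_pixels * config.pixel_size**2 * 1e-6

    @classmethod
    def full(cls, shape) -> "Roi":
        return cls(0, shape[0], 0, shape[1])


@dataclass(frozen=True)
class ModulationMap:
    values: np.ndarray          # per-pixel m in [0, 1]; NaN where invalid
    roi_median: float
    roi: Roi


@dataclass(frozen=True)
class AxialProfile:
    z: np.ndarray               # um, peak re-centered to 0
    intensity: np.ndarray       # peak-normalized mean sectioned ROI intensity


@dataclass(frozen=True)
class SnrReport:
    snr_uniform: float
    snr_sectioned: float
    ratio: float
    m_used: float


@dataclass(frozen=True)
class FrequencyEstimate:
    frequency: GridFrequency
    peak_power: float
    flagged: bool               # True when no grid peak rose above the floor


@dataclass(frozen=True)
class ContrastReport:
    mean_ratio: float
    per_target: np.ndarray
    std: float


def modulation_map(triplet: PhaseTriplet, roi: Optional[Roi] = None) -> ModulationMap:
    """Per-pixel modulation depth m = I_sectioned / I_widefield.

    Pixels with non-positive widefield intensity are flagged invalid
    (NaN) and excluded from the ROI median; values are clipped to [0, 1].
    """
    sect = sectioned_image(triplet).pixels
    wide = widefield_image(triplet).pixels
    roi = roi or Roi.full(wide.shape)
    roi.check_inside(wide.shape)
    values = np.full_like(wide, np.nan)
    valid = wide > 0
    values[valid] = np.clip(sect[valid] / wide[valid], 0.0, 1.0)
    window = values[roi.slice()]
    finite = window[np.isfinite(window)]
    if finite.size == 0:
        raise ValueError("no valid (positive-mean) pixels in the ROI")
    return ModulationMap(values=values, roi_median=float(np.median(finite)), roi=roi)


def _frame_sigma(triplet: PhaseTriplet, noise: Optional[NoiseModel],
                 mean_intensity: float) -> float:
    if noise is None:
        prov = triplet.provenance
        noise = NoiseModel(
            photon_scale=float(prov.get("photon_scale", 0.0)),
            read_sigma=float(prov.get("read_sigma", 0.0)),
        )
    sigma = noise.frame_sigma(mean_intensity)
    if sigma <= 0:
        raise ValueError("per-frame noise std is zero; SNR is undefined")
    return sigma


def snr_report(
    triplet: PhaseTriplet,
    m: Optional[float] = None,
    noise: Optional[NoiseModel] = None,
    roi: Optional[Roi] = None,
) -> SnrReport:
    """Uniform vs. sectioned SNR and their ratio at modulation depth m.

    ``m`` defaults to the ROI-median measured modulation depth; the
    per-frame noise std is taken from ``noise`` or the triplet's
    recorded noise model.  The ratio sqrt(2)/m falls as m rises: deeper
    modulation costs less SNR relative to the widefield image.
    """
    wide = widefield_image(triplet).pixels
    roi = roi or Roi.full(wide.shape)
    roi.check_inside(wide.shape)
    if m is None:
        m = modulation_map(triplet, roi).roi_median
    if not 0.0 < m <= 1.0:
        raise ValueError(f"modulation depth must lie in (0, 1], got {m}")
    mean_w = float(wide[roi.slice()].mean())
    sigma = _frame_sigma(triplet, noise, mean_w)
    snr_u = math.sqrt(3.0) * mean_w / sigma
    snr_s = math.sqrt(1.5) * m * mean_w / sigma
    return SnrReport(snr_uniform=snr_u, snr_sectioned=snr_s,
                     ratio=snr_u / snr_s, m_used=float(m))


def axial_profile(series, roi: Optional[Roi] = None,
                  z: Optional[Sequence[float]] = None) -> AxialProfile:
    """Mean sectioned ROI intensity vs. axial position.

    ``series`` is the (z, triplets) pair from ``render_axial_series`` or
    a plain list of triplets with ``z`` given separately.  The profile
    is normalized to its peak and the peak position re-centered to 0.
    """
    if z is None:
        z, triplets = series
    else:
        triplets = series
    z = np.asarray(z, dtype=float)
    if len(triplets) != z.size:
        raise ValueError("z and triplet list lengths differ")
    if z.size < 5:
        raise ValueError("need at least 5 axial positions to form a profile")
    roi = roi or Roi.full(triplets[0].shape)
    means = np.array([
        float(sectioned_image(t).pixels[roi.slice()].mean()) for t in triplets
    ])
    peak = means.max()
    if peak <= 0:
        raise ValueError("sectioned intensity vanished everywhere in the scan")
    i_peak = int(np.argmax(means))
    return AxialProfile(z=z - z[i_peak], intensity=means / peak)


def _half_crossing(z: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Distance from index 0 to the first 0.5 crossing (linear interp)."""
    for i in range(len(y) - 1):
        if y[i] >= 0.5 > y[i + 1]:
            frac = (y[i] - 0.5) / (y[i] - y[i + 1])
            return abs(z[i] + frac * (z[i + 1] - z[i]))
    return None


def section_thickness_from_profile(profile: AxialProfile) -> float:
    """Optical section thickness: axial distance to the 50 % intensity point.

    Linear interpolation between bracketing samples on each side of the
    peak; with both sides available the two one-sided half-widths are
    averaged (the convention matches the closed-form prediction).
    """
    i_peak = int(np.argmax(profile.intensity))
    right = _half_crossing(profile.z[i_peak:], profile.intensity[i_peak:])
    left = _half_crossing(profile.z[i_peak::-1], profile.intensity[i_peak::-1])
    sides = [s for s in (left, right) if s is not None]
    if not sides:
        raise ValueError(
            "profile never drops to 50% of its peak; widen the z range"
        )
    return float(np.mean(sides))


def section_thickness_subrois(series, roi: Roi, grid=(4, 2)):
    """Thickness over a grid of equal sub-ROIs: (mean, std, per-tile values).

    Mirrors the error-bar procedure of measuring the thickness in eight
    separate regions of the image stack (default 4 x 2 tiles).
    """
    z, triplets = series
    rows = np.linspace(roi.row0, roi.row1, grid[0] + 1).astype(int)
    cols = np.linspace(roi.col0, roi.col1, grid[1] + 1).astype(int)
    values = []
    for i in range(grid[0]):
        for j in range(grid[1]):
            tile = Roi(rows[i], rows[i + 1], cols[j], cols[j + 1])
            prof = axial_profile((z, triplets), roi=tile)
            values.append(section_thickness_from_profile(prof))
    values = np.asarray(values)
    return float(values.mean()), float(values.std()), values


def contrast_ratio(image: np.ndarray, target_rois: Sequence[Roi],
                   background_roi: Roi) -> ContrastReport:
    """Mean target-to-background intensity ratio over a set of targets."""
    image = np.asarray(image, dtype=float)
    background_roi.check_inside(image.shape)
    bg = float(image[background_roi.slice()].mean())
    if bg == 0:
        raise ValueError("background ROI has zero mean intensity")
    ratios = []
    for roi in target_rois:
        roi.check_inside(image.shape)
        ratios.append(float(image[roi.slice()].mean()) / bg)
    ratios = np.asarray(ratios)
    return ContrastReport(mean_ratio=float(ratios.mean()), per_target=ratios,
                          std=float(ratios.std()))


def estimate_frequency(image: np.ndarray, config: OpticalConfig,
                       peak_snr: float = 10.0) -> FrequencyEstimate:
    """Grid frequency from the dominant non-DC Fourier peak along x.

    Row-averaged, Hann-windowed, zero-padded power spectrum with a local
    quadratic sub-bin refinement, converted to mm^-1 through the pixel
    pitch.  Returns frequency 0 with ``flagged=True`` when no peak rises
    ``peak_snr``-fold above the median spectral floor.
    """
    image = np.asarray(image, dtype=float)
    cols = image.shape[1]
    if cols < 8:
        raise ValueError("image too small for frequency estimation")
    window = np.hanning(cols)
    padded = 8 * cols  # finer grid to tame leakage of non-integer periods
    spectrum = np.abs(
        np.fft.rfft((image - image.mean()) * window, n=padded, axis=1)
    ) ** 2
    power = spectrum.mean(axis=0)
    search = power.copy()
    search[: 3 * 8] = 0.0  # exclude DC and the window's main-lobe leakage
    k = int(np.argmax(search))
    floor = float(np.median(power))
    if search[k] <= 0 or (floor > 0 and search[k] < peak_snr * floor):
        zero = GridFrequency(0.0, 0.0)
        return FrequencyEstimate(frequency=zero, peak_power=float(search[k]),
                                 flagged=True)
    # quadratic sub-bin refinement on log power
    if 1 <= k < power.size - 1:
        y0, y1, y2 = np.log(power[k - 1:k + 2] + 1e-300)
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:  # pragma: no cover - peak at Nyquist edge
        delta = 0.0
    cycles_per_px = (k + delta) / padded
    nu_abs = cycles_per_px * 1000.0 / config.pixel_size
    freq = GridFrequency(nu_abs, normalized_frequency(nu_abs, config))
    return FrequencyEstimate(frequency=freq, peak_power=float(search[k]),
                             flagged=False)
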