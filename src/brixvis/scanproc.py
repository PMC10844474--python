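"""Multi-point scan processing.

A fruit moving past the detector yields a sequence of spectra ("points"),
the first and last of which are truncated by the acquisition geometry and
some of which may saturate the detector. This module reduces one such
K x P scan to a single effective spectrum by

1. trimming attenuated end points,
2. discarding saturated points,
3. scoring each remaining point's signal-to-noise ratio (SNR) against a
   sample-free background spectrum,
4. averaging the points with SNR-proportional weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

_SNR_EPS = 1e-12


class DegenerateScanError(ValueError):
    """Raised when every acquisition point of a scan is unusable."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis shared by all spectra (nm)."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavelength grid must be a 1-D array with >= 2 entries")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def default(cls, n_channels: int = 2047, lo: float = 560.0, hi: float = 1072.0) -> "WavelengthGrid":
        return cls(np.linspace(lo, hi, n_channels))


@dataclass
class MultiPointScan:
    """One fruit's K x P matrix of per-position transmission spectra."""

    sample_id: str
    orientation: str  # "O1" | "O2"
    points: np.ndarray  # K x P intensities, conveyor order
    grid: WavelengthGrid

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be a K x P matrix")
        if self.points.shape[0] < 1:
            raise ValueError("scan needs at least one acquisition point")
        if self.points.shape[1] != len(self.grid):
            raise ValueError(
                f"scan {self.sample_id}: {self.points.shape[1]} channels "
                f"!= grid length {len(self.grid)}"
            )
        if np.any(self.points < 0):
            raise ValueError(f"scan {self.sample_id}: negative intensities")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class BackgroundSpectrum:
    """Sample-free reference spectrum plus its channel-noise level."""

    intensity: np.ndarray
    noise_sd: float

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1:
            raise ValueError("background intensity must be 1-D")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PointQuality:
    """Per-point SNR, retention flag and normalized weight."""

    snr: np.ndarray
    weight: np.ndarray
    retained: np.ndarray


@dataclass
class Spectrum:
    """A single P-channel spectrum on a shared wavelength grid."""

    intensity: np.ndarray
    grid: WavelengthGrid
    sample_id: str = ""
    tags: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.grid),):
            raise ValueError("spectrum length must match grid")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("spectrum contains non-finite values")

    def with_tag(self, tag: str) -> "Spectrum":
        return replace(self, tags=self.tags + (tag,))


@dataclass(frozen=True)
class AggregationParams:
    """Knobs for :func:`aggregate_scan`."""

    rel_threshold: float = 0.5
    saturation_level: float = 65535.0
    max_saturated_frac: float = 0.01


def trim_end_scans(scan: MultiPointScan, rel_threshold: float = 0.5) -> MultiPointScan:
    """Drop contiguous leading/trailing points with low total intensity.

    A point is "incomplete" when its summed intensity falls below
    ``rel_threshold`` times the median point total. Only maximal runs at
    the two ends are removed; interior points are never touched.
    """
    if scan.n_points < 3:
        raise ValueError(f"scan {scan.sample_id}: need >= 3 points to trim ends")
    totals = scan.points.sum(axis=1)
    threshold = rel_threshold * np.median(totals)
    below = totals < threshold
    if below.all() or np.median(totals) <= 0:
        raise DegenerateScanError(
            f"scan {scan.sample_id}: all {scan.n_points} points below trim threshold"
        )
    lo = 0
    while below[lo]:
        lo += 1
    hi = scan.n_points
    while below[hi - 1]:
        hi -= 1
    if lo == 0 and hi == scan.n_points:
        return scan
    return replace(scan, points=scan.points[lo:hi])


def flag_saturated(
    scan: MultiPointScan, saturation_level: float, max_frac: float = 0.01
) -> np.ndarray:
    """Boolean retain-flags; a point is dropped when *more than* ``max_frac``
    of its channels sit at or above ``saturation_level``."""
    if saturation_level <= 0:
        raise ValueError("saturation_level must be positive")
    frac = (scan.points >= saturation_level).mean(axis=1)
    return frac <= max_frac


def estimate_snr(point: np.ndarray, background: BackgroundSpectrum) -> float:
    """Mean net signal over the background noise SD (linear scale, >= 0)."""
    point = np.asarray(point, dtype=float)
    if point.shape != background.intensity.shape:
        raise ValueError(
            f"point has {point.size} channels, background has {background.intensity.size}"
        )
    net = np.maximum(point - background.intensity, 0.0)
    return float(net.mean() / max(background.noise_sd, _SNR_EPS))


def compute_weights(snrs: np.ndarray, retained: np.ndarray) -> np.ndarray:
    """SNR-proportional weights over retained points, normalized to sum 1.

    All retained SNRs zero falls back to uniform weights with a warning.
    """
    snrs = np.asarray(snrs, dtype=float)
    retained = np.asarray(retained, dtype=bool)
    if snrs.shape != retained.shape:
        raise ValueError("snrs and retained flags must have equal length")
    if not retained.any():
        raise DegenerateScanError("no retained points to weight")
    weights = np.where(retained, snrs, 0.0)
    total = weights.sum()
    if total <= 0:
        warnings.warn(
            "all retained points have zero SNR; falling back to uniform weights",
            stacklevel=2,
        )
        weights = retained.astype(float)
        total = weights.sum()
    return weights / total


def weighted_average(scan: MultiPointScan, weights: np.ndarray) -> Spectrum:
    """Channel-wise convex combination of the scan's point spectra."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (scan.n_points,):
        raise ValueError(
            f"{weights.size} weights for {scan.n_points} points (scan {scan.sample_id})"
        )
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    return Spectrum(
        intensity=weights @ scan.points,
        grid=scan.grid,
        sample_id=scan.sample_id,
        tags=("aggregated",),
    )


def aggregate_scan(
    scan: MultiPointScan,
    background: BackgroundSpectrum,
    params: AggregationParams = AggregationParams(),
) -> Spectrum:
    """Trim ends, drop saturated points, SNR-weight and average."""
    trimmed = trim_end_scans(scan, params.rel_threshold) if scan.n_points >= 3 else scan
    retained = flag_saturated(trimmed, params.saturation_level, params.max_saturated_frac)
    if not retained.any():
        raise DegenerateScanError(f"scan {scan.sample_id}: every point saturated")
    snrs = np.array([estimate_snr(pt, background) for pt in trimmed.points])
    weights = compute_weights(snrs, retained)
    logger.debug(
        "scan %s: K=%d->%d, SNRs=%s, weights=%s",
        scan.sample_id, scan.n_points, trimmed.n_points,
        np.round(snrs, 3), np.round(weights, 4),
    )
    return weighted_average(trimmed, weights)
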