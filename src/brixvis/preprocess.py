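"""Spectral pretreatments: Savitzky-Golay smoothing, SNV, or raw pass-through.

Exactly one pretreatment is applied per model variant; SG and SNV are
alternatives, never chained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs

METHODS = ("RAW", "SG", "SNV")


class ZeroVarianceError(ValueError):
    """SNV of a constant spectrum is undefined."""


@dataclass(frozen=True)
class PretreatmentSpec:
    method: str = "RAW"
    sg_window: int = 13
    sg_polyorder: int = 2

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")


def sg_smooth(x: np.ndarray, window: int = 13, polyorder: int = 2) -> np.ndarray:
    """Windowed least-squares polynomial smoothing.

    Interior channels use the standard central SG convolution. Edge
    channels are fitted on their *truncated* window (whatever part of the
    window lies inside the spectrum) and the polynomial is evaluated at
    the channel position, so polynomials up to ``polyorder`` are
    reproduced exactly everywhere, edges included.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D spectrum")
    p = x.size
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if window > p:
        raise ValueError(f"window {window} exceeds spectrum length {p}")
    half = window // 2
    coeffs = savgol_coeffs(window, polyorder)
    # np.convolve flips the kernel; SG kernels are symmetric so this is safe.
    out = np.convolve(x, coeffs, mode="same")
    # Re-do the edges with one-sided truncated-window fits.
    for i in list(range(half)) + list(range(p - half, p)):
        lo, hi = max(0, i - half), min(p, i + half + 1)
        t = np.arange(lo, hi) - i
        design = np.vander(t, polyorder + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(design, x[lo:hi], rcond=None)
        out[i] = beta[0]
    return out


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and unit-SD scaling."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(float(x.mean()))):
        raise ZeroVarianceError("cannot SNV-transform a constant spectrum")
    return (x - x.mean()) / sd


def apply_pretreatment(matrix: np.ndarray, spec: PretreatmentSpec,
                       sample_ids=None) -> np.ndarray:
    """Row-wise pretreatment of an n x P spectra matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected an n x P matrix")
    if spec.method == "RAW":
        return matrix.copy()
    out = np.empty_like(matrix)
    for i, row in enumerate(matrix):
        try:
            if spec.method == "SG":
                out[i] = sg_smooth(row, spec.sg_window, spec.sg_polyorder)
            else:
                out[i] = snv(row)
        except ValueError as exc:
            sid = sample_ids[i] if sample_ids is not None else f"row {i}"
            raise type(exc)(f"{spec.method} failed for {sid}: {exc}") from exc
    return out
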