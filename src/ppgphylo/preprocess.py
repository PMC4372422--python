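"""Baseline removal and smoothing of raw pulse-wave recordings.

Finger-PPG amplitude series drift slowly as the optical sensor settles; the
drift is removed by subtracting a low-order least-squares polynomial fit
(degree 6 by default) over the sample index, and the detrended wave is then
smoothed with a Savitzky-Golay filter. The detrend-then-smooth order is the
default pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.signal import savgol_filter

from .signal_io import Signal

__all__ = ["PreprocessConfig", "detrend_poly", "smooth_sg", "preprocess"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for the two-stage preprocessing.

    detrend_degree : degree of the baseline polynomial (>= 0, default 6).
    sg_window : odd Savitzky-Golay window length in samples (default 11).
    sg_polyorder : local polynomial order, < sg_window (default 3).
    """

    detrend_degree: int = 6
    sg_window: int = 11
    sg_polyorder: int = 3

    def __post_init__(self) -> None:
        if self.detrend_degree < 0:
            raise ValueError("detrend_degree must be >= 0")
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ValueError("sg_window must be an odd integer >= 3")
        if not 0 <= self.sg_polyorder < self.sg_window:
            raise ValueError("sg_polyorder must satisfy 0 <= polyorder < window")


def detrend_poly(signal: Signal, degree: int = 6) -> Signal:
    """Subtract the least-squares polynomial fit of ``degree`` from a signal.

    The abscissa is the sample index, centered and scaled internally for
    conditioning (a degree-6 Vandermonde on raw indices of a multi-thousand
    sample record is numerically hopeless). The residual is returned with the
    input's metadata.
    """
    n = len(signal)
    if degree >= n:
        raise ValueError(f"detrend degree {degree} must be < signal length {n}")
    t = np.arange(n, dtype=float)
    # Polynomial.fit maps t to [-1, 1] before solving.
    fit = Polynomial.fit(t, signal.samples, deg=degree)
    return signal.with_samples(signal.samples - fit(t))


def smooth_sg(signal: Signal, window: int = 11, polyorder: int = 3) -> Signal:
    """Savitzky-Golay smoothing: per-window least-squares polynomial fits.

    Edges use scipy's ``interp`` mode, i.e. the boundary polynomial fits are
    evaluated directly instead of mirroring samples, so low-degree polynomial
    signals pass through exactly over the full length.
    """
    n = len(signal)
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if polyorder >= window:
        raise ValueError("Savitzky-Golay polyorder must be < window")
    if window > n:
        raise ValueError(f"window {window} exceeds signal length {n}")
    return signal.with_samples(
        savgol_filter(signal.samples, window_length=window, polyorder=polyorder,
                      mode="interp")
    )


def preprocess(signal: Signal, config: PreprocessConfig | None = None) -> Signal:
    """Detrend then smooth, exactly ``smooth_sg(detrend_poly(x))``."""
    config = config or PreprocessConfig()
    detrended = detrend_poly(signal, config.detrend_degree)
    return smooth_sg(detrended, config.sg_window, config.sg_polyorder)
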