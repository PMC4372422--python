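"""Order-p all-pole (LPC) modelling of a preprocessed pulse wave.

A signal x is summarized by the autoregressive model

    |S(w)|^2 = sigma^2 / |1 + a_1 e^{-jw} + ... + a_p e^{-jpw}|^2,

fitted by the autocorrelation method: the biased sample autocorrelation
r(0..p) feeds the Levinson-Durbin recursion, which solves the Yule-Walker
equations and guarantees a minimum-phase polynomial (all reflection
coefficients inside the unit circle). One model is fitted per whole record;
there is no framing. The model's log-spectrum Fourier coefficients (the LPC
cepstrum) are obtained from the coefficient recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz
from scipy.signal import lfilter

from .signal_io import Signal

__all__ = [
    "LPCModel",
    "DegenerateSignalError",
    "autocorrelation",
    "levinson_durbin",
    "fit_lpc",
    "lpc_power_spectrum",
    "spectrum_grid",
    "cepstrum_from_lpc",
    "model_autocorrelation",
    "DEFAULT_ORDER",
    "DEFAULT_GRID",
]

#: LPC order used throughout the study.
DEFAULT_ORDER = 12
#: Number of frequency points spanning [0, pi] for spectral quadrature.
DEFAULT_GRID = 1024


class DegenerateSignalError(ValueError):
    """Signal has no usable power (zero variance) or an invalid autocorrelation."""


@dataclass(frozen=True)
class LPCModel:
    """All-pole model: coefficients a_1..a_p, error power sigma^2, source r(0..p).

    The implied prediction polynomial is A(z) = 1 + sum_i a_i z^{-i}; sigma^2
    equals a^T R a with a = (1, a_1..a_p) and R the Toeplitz matrix of r.
    """

    order: int
    a: np.ndarray  # a_1 .. a_p
    sigma2: float
    r: np.ndarray  # r(0) .. r(p)
    reflection: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if a.shape != (self.order,):
            raise ValueError(f"expected {self.order} coefficients, got {a.shape}")
        if r.shape != (self.order + 1,):
            raise ValueError(f"expected r(0..{self.order}), got {r.shape}")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "r", r)
        if self.reflection is not None:
            object.__setattr__(
                self, "reflection", np.asarray(self.reflection, dtype=float)
            )

    @property
    def a_full(self) -> np.ndarray:
        """The monic coefficient vector (1, a_1, ..., a_p)."""
        return np.concatenate(([1.0], self.a))

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "a": self.a.tolist(),
            "sigma2": self.sigma2,
            "r": self.r.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LPCModel":
        return cls(int(d["order"]), np.asarray(d["a"]), float(d["sigma2"]),
                   np.asarray(d["r"]))


def autocorrelation(signal: Signal | np.ndarray, maxlag: int) -> np.ndarray:
    """Biased sample autocorrelation r(k) = (1/N) sum_t x_t x_{t+k}, k = 0..maxlag.

    The biased (1/N) normalization keeps the implied Toeplitz matrix positive
    semi-definite, which the Levinson-Durbin recursion requires. An all-zero
    signal yields r identically zero (the degenerate case is flagged at model
    fitting, not here).
    """
    x = signal.samples if isinstance(signal, Signal) else np.asarray(signal, float)
    n = x.size
    if maxlag >= n:
        raise ValueError(f"maxlag {maxlag} must be < signal length {n}")
    # maxlag is small (the LPC order): direct dot products beat an FFT here.
    return np.array([x[: n - k] @ x[k:] for k in range(maxlag + 1)]) / n


def levinson_durbin(r: np.ndarray, p: int) -> LPCModel:
    """Solve the Yule-Walker equations for an order-p model by Levinson-Durbin.

    Returns the model whose coefficients minimize the one-step prediction
    error implied by r; sigma2 is the recursion's final error power. Raises
    :class:`DegenerateSignalError` if r(0) <= 0 or r is not positive definite
    up to order p (the failing order is named).
    """
    r = np.asarray(r, dtype=float)
    if r.size < p + 1:
        raise ValueError(f"need r(0..{p}), got {r.size} values")
    if not r[0] > 0:
        raise DegenerateSignalError("r(0) <= 0: signal has no power")
    a = np.zeros(p)
    k = np.zeros(p)
    err = r[0]
    for i in range(1, p + 1):
        acc = r[i] + a[: i - 1] @ r[1:i][::-1]
        ki = -acc / err
        if not np.abs(ki) < 1.0 + 1e-12:
            raise DegenerateSignalError(
                f"autocorrelation not positive definite at order {i}"
            )
        a_prev = a[: i - 1].copy()
        a[: i - 1] = a_prev + ki * a_prev[::-1]
        a[i - 1] = ki
        k[i - 1] = ki
        err *= 1.0 - ki * ki
        if not err > 0:
            raise DegenerateSignalError(
                f"prediction error vanished at order {i} (degenerate signal)"
            )
    return LPCModel(order=p, a=a[:p].copy(), sigma2=float(err), r=r[: p + 1].copy(),
                    reflection=k)


def fit_lpc(signal: Signal, p: int = DEFAULT_ORDER) -> LPCModel:
    """Autocorrelation-method LPC fit of order p over the whole record."""
    n = len(signal)
    if n < 2 * (p + 1):
        raise ValueError(
            f"signal {signal.label!r} has {n} samples; need >= {2 * (p + 1)} "
            f"for order-{p} LPC"
        )
    try:
        return levinson_durbin(autocorrelation(signal, p), p)
    except DegenerateSignalError as exc:
        raise DegenerateSignalError(f"signal {signal.label!r}: {exc}") from exc


def spectrum_grid(G: int = DEFAULT_GRID) -> np.ndarray:
    """G frequencies uniformly spanning [0, pi] inclusive."""
    if G < 2:
        raise ValueError("grid must have at least 2 points")
    return np.linspace(0.0, np.pi, G)


def lpc_power_spectrum(model: LPCModel, G: int | np.ndarray = DEFAULT_GRID) -> np.ndarray:
    """Model power spectrum sigma^2 / |A(w)|^2 on a grid over [0, pi].

    Real signals have even spectra, so the [0, pi] half fully represents
    [-pi, pi]. All values are strictly positive for a minimum-phase model;
    a pole on the unit circle (|A| = 0 at a grid point) is an error.
    """
    omega = spectrum_grid(G) if np.isscalar(G) else np.asarray(G, dtype=float)
    # A(w) = sum_k a_k e^{-jkw}, a_0 = 1
    A = np.exp(-1j * np.outer(omega, np.arange(model.order + 1))) @ model.a_full
    mag2 = np.abs(A) ** 2
    if np.any(mag2 == 0.0):
        raise ValueError("pole on the unit circle: |A(w)| = 0 at a grid point")
    return model.sigma2 / mag2


def cepstrum_from_lpc(model: LPCModel, L: int) -> np.ndarray:
    """Cepstral coefficients c_0..c_L of the model log-spectrum.

    c_0 = log sigma^2 and, with a_k = 0 beyond the model order,

        c_n = -a_n - (1/n) sum_{k=1}^{n-1} k c_k a_{n-k},   n >= 1,

    so c_1 = -a_1. These are the Fourier coefficients of log|S(w)|^2 for the
    minimum-phase model (c_{-n} = c_n).
    """
    if L < 1:
        raise ValueError("cepstral truncation L must be >= 1")
    a = np.zeros(L + 1)
    upto = min(L, model.order)
    a[1 : upto + 1] = model.a[:upto]
    c = np.zeros(L + 1)
    c[0] = np.log(model.sigma2)
    for n in range(1, L + 1):
        acc = a[n]
        for k in range(1, n):
            acc += (k / n) * c[k] * a[n - k]
        c[n] = -acc
    return c


def model_autocorrelation(model: LPCModel, maxlag: int,
                          n_impulse: int = 8192) -> np.ndarray:
    """Autocovariance r(0..maxlag) implied by the model itself.

    Computed from the impulse response h of 1/A(z): r(k) = sigma^2 sum_t
    h_t h_{t+k}, truncated at ``n_impulse`` terms (plenty for the
    well-damped minimum-phase models this package fits).
    """
    impulse = np.zeros(n_impulse)
    impulse[0] = 1.0
    h = lfilter([1.0], model.a_full, impulse)
    return model.sigma2 * np.array(
        [h[: n_impulse - k] @ h[k:] for k in range(maxlag + 1)]
    )


def toeplitz_autocorrelation(r: np.ndarray) -> np.ndarray:
    """The symmetric Toeplitz matrix R built from r(0..p)."""
    return toeplitz(np.asarray(r, dtype=float))
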