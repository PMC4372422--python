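"""Spectral-distortion measures between all-pole pulse-wave models.

Five measures compare two LPC spectra P(w) = sigma^2/|A(w)|^2 and
P'(w) = sigma'^2/|A'(w)|^2:

ISD   Itakura-Saito distortion, (1/2pi) int [P/P' + log(P'/P) - 1] dw; an
      asymmetric divergence, zero iff the spectra coincide.
ID    Itakura (log-likelihood ratio) distortion, the gain-optimized ISD with
      closed form log(a^T R' a / sigma'^2), where a are the first model's
      monic coefficients and R' the Toeplitz autocorrelation matrix of the
      second signal. Asymmetric; >= 0 because a' minimizes the quadratic
      form over monic vectors.
ID_s  Symmetrized Itakura, (ID(S,S') + ID(S',S)) / 2.
LSD   Log spectral distortion, the L_m norm of log P - log P' (natural log,
      gains included); m = 2 is the root-mean-square variant used throughout.
WCD   Weighted cepstral distortion, sum_{n=1..L} w(n) (c_n - c'_n)^2 with the
      sine lifter w(n) = 1 + h sin(n pi / L).

Spectral integrals use trapezoidal quadrature on a uniform grid over
[0, pi] (even integrands, so the half-axis represents [-pi, pi]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .lpc import (
    DEFAULT_GRID,
    DEFAULT_ORDER,
    LPCModel,
    cepstrum_from_lpc,
    fit_lpc,
    lpc_power_spectrum,
    spectrum_grid,
    toeplitz_autocorrelation,
)
from .signal_io import DissimilarityMatrix, Signal

__all__ = [
    "DistortionConfig",
    "MEASURES",
    "itakura_saito",
    "itakura",
    "itakura_symmetric",
    "log_spectral",
    "weighted_cepstral",
    "model_distortion",
    "dissimilarity_matrix",
]

#: Measure names accepted by the config, in the canonical reporting order.
MEASURES = ("ISD", "ID", "ID_s", "LSD", "WCD")


@dataclass(frozen=True)
class DistortionConfig:
    """Parameters of a distortion computation.

    measure : one of :data:`MEASURES`.
    p : LPC order (default 12).
    m : LSD norm exponent; 2 gives the root-mean-square variant.
    L : cepstral truncation for WCD; defaults to p - 1.
    h : lifter height; defaults to L / 2.
    grid : number of quadrature points over [0, pi].
    """

    measure: str = "ID"
    p: int = DEFAULT_ORDER
    m: int = 2
    L: int | None = None
    h: float | None = None
    grid: int = DEFAULT_GRID

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; choose from {MEASURES}")
        if self.m < 1:
            raise ValueError("LSD exponent m must be >= 1")
        if self.cepstral_L < 1:
            raise ValueError("cepstral truncation L must be >= 1")
        if self.lifter_h < 0:
            raise ValueError("lifter height h must be >= 0")

    @property
    def cepstral_L(self) -> int:
        return self.L if self.L is not None else self.p - 1

    @property
    def lifter_h(self) -> float:
        return self.h if self.h is not None else self.cepstral_L / 2.0


def _halfline_mean(values: np.ndarray) -> float:
    """(1/2pi) int_{-pi}^{pi} f dw for an even f sampled on [0, pi]."""
    return float(np.trapezoid(values, dx=np.pi / (values.size - 1)) / np.pi)


def itakura_saito(modelS: LPCModel, modelSp: LPCModel,
                  G: int = DEFAULT_GRID) -> float:
    """Itakura-Saito divergence of the two model spectra (asymmetric, >= 0)."""
    omega = spectrum_grid(G)
    P = lpc_power_spectrum(modelS, omega)
    Pp = lpc_power_spectrum(modelSp, omega)
    ratio = P / Pp
    return _halfline_mean(ratio - np.log(ratio) - 1.0)


def itakura(modelS: LPCModel, modelSp: LPCModel) -> float:
    """Itakura distortion ID(S, S') = log(a^T R' a / sigma'^2).

    R' is the Toeplitz matrix of the second model's stored autocorrelation
    and sigma'^2 = a'^T R' a' is recomputed from it, so a self-comparison is
    exactly zero. Generally ID(S, S') != ID(S', S).
    """
    if modelS.order != modelSp.order:
        raise ValueError("models must share the same LPC order")
    Rp = toeplitz_autocorrelation(modelSp.r)
    a = modelS.a_full
    ap = modelSp.a_full
    num = float(a @ Rp @ a)
    den = float(ap @ Rp @ ap)
    if not den > 0:
        raise ValueError("singular autocorrelation matrix in Itakura distortion")
    return float(np.log(num / den))


def itakura_symmetric(modelS: LPCModel, modelSp: LPCModel) -> float:
    """Symmetrized Itakura distortion (arithmetic mean of both directions)."""
    return 0.5 * (itakura(modelS, modelSp) + itakura(modelSp, modelS))


def log_spectral(modelS: LPCModel, modelSp: LPCModel, m: int = 2,
                 G: int = DEFAULT_GRID) -> float:
    """L_m log spectral distortion [(1/2pi) int |log P - log P'|^m dw]^{1/m}."""
    if m < 1:
        raise ValueError("m must be >= 1")
    omega = spectrum_grid(G)
    V = np.log(lpc_power_spectrum(modelS, omega)) - np.log(
        lpc_power_spectrum(modelSp, omega)
    )
    return _halfline_mean(np.abs(V) ** m) ** (1.0 / m)


def weighted_cepstral(modelS: LPCModel, modelSp: LPCModel,
                      L: int | None = None, h: float | None = None) -> float:
    """Lifter-weighted squared cepstral distance sum_{n=1..L} w(n)(c_n - c'_n)^2.

    w(n) = 1 + h sin(n pi / L); defaults L = p - 1 and h = L / 2. c_0 (the
    gain term) is excluded.
    """
    if L is None:
        L = modelS.order - 1
    if L < 1:
        raise ValueError("cepstral truncation L must be >= 1")
    if h is None:
        h = L / 2.0
    n = np.arange(1, L + 1)
    w = 1.0 + h * np.sin(n * np.pi / L)
    dc = cepstrum_from_lpc(modelS, L)[1:] - cepstrum_from_lpc(modelSp, L)[1:]
    return float(w @ (dc * dc))


def model_distortion(modelS: LPCModel, modelSp: LPCModel,
                     config: DistortionConfig) -> float:
    """Dispatch a configured measure on a fitted model pair."""
    if config.measure == "ISD":
        return itakura_saito(modelS, modelSp, config.grid)
    if config.measure == "ID":
        return itakura(modelS, modelSp)
    if config.measure == "ID_s":
        return itakura_symmetric(modelS, modelSp)
    if config.measure == "LSD":
        return log_spectral(modelS, modelSp, config.m, config.grid)
    return weighted_cepstral(modelS, modelSp, config.cepstral_L, config.lifter_h)


def dissimilarity_matrix(signals: Mapping[str, Signal] | Iterable[Signal],
                         config: DistortionConfig) -> DissimilarityMatrix:
    """Pairwise distortion matrix over a labelled signal set.

    One LPC model is fitted per signal. For the asymmetric measures (ID, ISD)
    the symmetrized value populates the matrix — ID_s for ID, the two-way
    mean for ISD — so the result is always valid UPGMA input. The diagonal
    is zero by construction.
    """
    if isinstance(signals, Mapping):
        items = [(label, sig) for label, sig in signals.items()]
    else:
        items = [(sig.label, sig) for sig in signals]
    if len(items) < 2:
        raise ValueError("need at least two signals for a dissimilarity matrix")
    labels = tuple(label for label, _ in items)
    models = [fit_lpc(sig, config.p) for _, sig in items]
    n = len(models)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if config.measure in ("ID", "ID_s"):
                d = itakura_symmetric(models[i], models[j])
            elif config.measure == "ISD":
                d = 0.5 * (
                    itakura_saito(models[i], models[j], config.grid)
                    + itakura_saito(models[j], models[i], config.grid)
                )
            else:
                d = model_distortion(models[i], models[j], config)
            # numerical round-off can leave a tiny negative residue
            D[i, j] = D[j, i] = max(d, 0.0)
    return DissimilarityMatrix(labels, D)
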