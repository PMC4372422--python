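import numpy as np
import pytest
from statsmodels.tsa.arima_process import arma_acovf

from ppgphylo.lpc import LPCModel


def model_from_coeffs(a, sigma2, reflection=None):
    """LPC model whose stored r is the exact model-implied autocovariance.

    Exact self-consistency matters for the oracle tests: Levinson-Durbin on
    this r reproduces a and sigma2, and the Itakura closed form equals the
    spectral-integral form to quadrature precision.
    """
    a = np.asarray(a, dtype=float)
    r = arma_acovf(np.concatenate(([1.0], a)), [1.0], nobs=a.size + 1,
                   sigma2=float(sigma2))
    return LPCModel(order=a.size, a=a, sigma2=float(sigma2),
                    r=np.asarray(r, dtype=float), reflection=reflection)


def model_from_reflections(k, sigma2):
    """Build a model from reflection coefficients (|k_i| < 1) by step-up."""
    k = np.asarray(k, dtype=float)
    p = k.size
    a = np.zeros(p)
    for i in range(1, p + 1):
        prev = a[: i - 1].copy()
        a[: i - 1] = prev + k[i - 1] * prev[::-1]
        a[i - 1] = k[i - 1]
    return model_from_coeffs(a, sigma2, reflection=k)


def random_minimum_phase_model(rng, p=12, rmax=0.95, rmin=0.2):
    """Random stable all-pole model with pole radii bounded by rmax.

    Bounded radii keep the spectrum resolvable on the quadrature grids the
    oracle tests use; the model is minimum-phase by construction.
    """
    if p % 2:
        raise ValueError("use an even order (conjugate pole pairs)")
    radii = rng.uniform(rmin, rmax, p // 2)
    angles = rng.uniform(0.05, np.pi - 0.05, p // 2)
    poles = radii * np.exp(1j * angles)
    coeffs = np.real(np.poly(np.concatenate([poles, np.conj(poles)])))
    sigma2 = float(np.exp(rng.normal(0.0, 0.5)))
    return model_from_coeffs(coeffs[1:], sigma2)


@pytest.fixture
def make_random_model():
    """Factory fixture for random minimum-phase models with exact r."""

    def make(rng, p=12, rmax=0.95):
        return random_minimum_phase_model(rng, p=p, rmax=rmax)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
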