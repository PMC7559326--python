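"""Dynamic light scattering: forward ACF model, cumulant sizing,
regularised size-distribution inversion and scattering-ratio aggregation
estimates.

The field autocorrelation of a polydisperse sphere population is a sum
of exponentials over the intensity-weighted diffusion spectrum,

    g1(tau) = sum_i w_i exp(-q^2 D_i tau),

with D_i from Stokes-Einstein and q from the scattering geometry.  The
measured intensity correlation follows the Siegert relation
g2 - 1 = beta g1^2.  Inversion of g1 onto a log-spaced diameter grid is
a non-negative Tikhonov-regularised least-squares problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from . import constants as C
from .exceptions import FeatureNotFoundError, ValidationError

__all__ = [
    "ACFTrace", "SizeDistribution", "ScatteringSummary",
    "scattering_vector", "stokes_einstein_diameter", "diffusion_from_diameter",
    "field_acf_model", "siegert", "cumulant_fit", "invert_distribution",
    "normalized_scattering", "CumulantSizer", "DistributionInverter",
    "default_diameter_grid",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ACFTrace:
    """Intensity autocorrelation trace (g2 - 1) on a lag grid."""

    lags_s: np.ndarray
    g2m1: np.ndarray
    beta: float = 0.9
    q_per_m: float | None = None
    temperature_K: float = C.ROOM_TEMPERATURE_K
    viscosity_Pa_s: float = C.WATER_VISCOSITY_PA_S

    def __post_init__(self):
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.g2m1 = np.asarray(self.g2m1, dtype=float)
        if self.lags_s.shape != self.g2m1.shape:
            raise ValidationError("lag and g2m1 arrays differ in length")
        if np.any(np.diff(self.lags_s) <= 0) or np.any(self.lags_s <= 0):
            raise ValidationError("lags must be positive and strictly increasing")
        if not 0 < self.beta <= 1:
            raise ValidationError("coherence factor beta must be in (0, 1]")
        if self.q_per_m is None:
            self.q_per_m = scattering_vector()


@dataclass
class SizeDistribution:
    """Intensity-weighted hydrodynamic-diameter distribution."""

    diameters_nm: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.diameters_nm = np.asarray(self.diameters_nm, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.diameters_nm.shape != self.weights.shape:
            raise ValidationError("diameters and weights differ in length")
        if np.any(self.diameters_nm <= 0):
            raise ValidationError("diameters must be positive")
        if np.any(self.weights < 0):
            raise ValidationError("weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValidationError("distribution has zero total weight")
        self.weights = self.weights / total

    def mean_diameter_nm(self) -> float:
        """z-average: intensity-weighted harmonic mean diameter."""
        return float(1.0 / np.sum(self.weights / self.diameters_nm))

    def mode_diameter_nm(self) -> float:
        return float(self.diameters_nm[int(np.argmax(self.weights))])


@dataclass(frozen=True)
class ScatteringSummary:
    mean_diameter_nm: float
    normalized_intensity: float
    est_aggregation_number: float


# ---------------------------------------------------------------------------
# elementary relations
# ---------------------------------------------------------------------------

def scattering_vector(angle_deg: float = C.DLS_SCATTERING_ANGLE_DEG,
                      wavelength_nm: float = C.DLS_WAVELENGTH_NM,
                      n_medium: float = C.DLS_MEDIUM_INDEX) -> float:
    """Scattering-vector magnitude q = 4 pi n sin(theta/2) / lambda, 1/m."""
    return (4.0 * np.pi * n_medium
            * np.sin(np.deg2rad(angle_deg) / 2.0) / (wavelength_nm * 1e-9))


def stokes_einstein_diameter(D_m2_s: float, temperature_K: float = C.ROOM_TEMPERATURE_K,
                             viscosity_Pa_s: float = C.WATER_VISCOSITY_PA_S) -> float:
    """Hydrodynamic diameter (nm) of a sphere with diffusivity D."""
    if D_m2_s <= 0 or temperature_K <= 0 or viscosity_Pa_s <= 0:
        raise ValidationError("D, T and viscosity must be positive")
    d_m = C.BOLTZMANN_J_K * temperature_K / (3.0 * np.pi * viscosity_Pa_s * D_m2_s)
    return d_m * 1e9


def diffusion_from_diameter(d_nm: float, temperature_K: float = C.ROOM_TEMPERATURE_K,
                            viscosity_Pa_s: float = C.WATER_VISCOSITY_PA_S) -> float:
    """Inverse of :func:`stokes_einstein_diameter` (m^2/s)."""
    if d_nm <= 0:
        raise ValidationError("diameter must be positive")
    return C.BOLTZMANN_J_K * temperature_K / (3.0 * np.pi * viscosity_Pa_s * d_nm * 1e-9)


def field_acf_model(dist: SizeDistribution, lags_s,
                    q_per_m: float | None = None,
                    temperature_K: float = C.ROOM_TEMPERATURE_K,
                    viscosity_Pa_s: float = C.WATER_VISCOSITY_PA_S) -> np.ndarray:
    """g1 on the lag grid for an intensity-weighted sphere population."""
    lags_s = np.asarray(lags_s, dtype=float)
    if q_per_m is None:
        q_per_m = scattering_vector()
    D = np.array([diffusion_from_diameter(d, temperature_K, viscosity_Pa_s)
                  for d in dist.diameters_nm])
    rates = q_per_m ** 2 * D
    return np.sum(dist.weights[:, None] * np.exp(-np.outer(rates, lags_s)), axis=0)


def siegert(g1, beta: float) -> np.ndarray:
    """Siegert relation: g2 - 1 = beta * g1^2."""
    if not 0 < beta <= 1:
        raise ValidationError("beta must be in (0, 1]")
    return beta * np.asarray(g1, dtype=float) ** 2


def normalized_scattering(I_sample: float, I_pristine: float,
                          mean_diameter_nm: float = np.nan) -> ScatteringSummary:
    """Aggregation-number estimate from the scattered-intensity ratio.

    With particle concentration fixed and intraparticle interference
    neglected, scattered intensity is proportional to the aggregate
    molecular weight, so I/I_pristine estimates particles per aggregate.
    """
    if I_pristine <= 0:
        raise ValidationError("pristine intensity must be positive")
    ratio = I_sample / I_pristine
    return ScatteringSummary(mean_diameter_nm, ratio, ratio)


# ---------------------------------------------------------------------------
# cumulant analysis
# ---------------------------------------------------------------------------

class CumulantSizer(BaseEstimator):
    """Second-order cumulant fit of ln(g2 - 1).

    Fits ln(g2-1) = ln beta - 2 Gbar tau + mu2 tau^2 by weighted
    polynomial least squares over the usable decay (g2-1 above
    ``rel_floor`` of its initial value).  Fitted attributes:

    - ``D_`` mean diffusion coefficient Gbar/q^2 (m^2/s)
    - ``diameter_nm_`` Stokes-Einstein z-average diameter
    - ``pdi_`` polydispersity index mu2/Gbar^2
    - ``beta_`` fitted coherence factor
    """

    def __init__(self, max_order: int = 2, rel_floor: float = 0.05):
        self.max_order = max_order
        self.rel_floor = rel_floor

    def fit(self, X, y=None):
        trace = X if isinstance(X, ACFTrace) else ACFTrace(*X)
        g = trace.g2m1
        if g[0] <= 0 or g[0] < 0.05 * trace.beta:
            raise FeatureNotFoundError("trace does not start near beta: no decay")
        # use only the leading contiguous decay: once the signal first
        # drops below the floor the remaining lags are noise-dominated
        below = np.flatnonzero(g <= self.rel_floor * g[0])
        stop = below[0] if below.size else g.size
        sel = np.zeros(g.size, dtype=bool)
        sel[:stop] = g[:stop] > 0
        if sel.sum() < 10:
            raise FeatureNotFoundError("fewer than 10 usable lags in the decay")
        tau = trace.lags_s[sel]
        lng = np.log(g[sel])
        deg = 2 if self.max_order >= 2 else 1
        # weights ~ g: delta(ln g) = delta(g)/g for uniform additive noise
        coeffs = np.polynomial.polynomial.polyfit(tau, lng, deg, w=g[sel])
        gbar = -coeffs[1] / 2.0
        if gbar <= 0:
            raise FeatureNotFoundError("non-decaying trace")
        mu2 = coeffs[2] if deg == 2 else 0.0
        self.beta_ = float(np.exp(coeffs[0]))
        self.gamma_bar_ = float(gbar)
        self.D_ = float(gbar / trace.q_per_m ** 2)
        self.pdi_ = float(mu2 / gbar ** 2)
        self.diameter_nm_ = stokes_einstein_diameter(
            self.D_, trace.temperature_K, trace.viscosity_Pa_s)
        return self


def cumulant_fit(trace: ACFTrace, max_order: int = 2):
    """Functional wrapper: returns (D m^2/s, PDI, beta)."""
    sizer = CumulantSizer(max_order=max_order).fit(trace)
    return sizer.D_, sizer.pdi_, sizer.beta_


# ---------------------------------------------------------------------------
# regularised inversion
# ---------------------------------------------------------------------------

def default_diameter_grid(n: int = 64, d_min_nm: float = 1.0,
                          d_max_nm: float = 5000.0) -> np.ndarray:
    return np.geomspace(d_min_nm, d_max_nm, n)


class DistributionInverter(BaseEstimator):
    """Non-negative Tikhonov inversion of g1 on an exponential dictionary.

    Solves  min_w ||A w - g1||^2 + alpha ||w||^2,  w >= 0,  where
    A_ij = exp(-q^2 D(d_j) tau_i) over a log-spaced diameter grid.
    ``alpha=None`` selects the regularisation strength by an L-curve
    corner heuristic.  Fitted attribute: ``distribution_``.
    """

    def __init__(self, grid_nm=None, alpha: float | None = None):
        self.grid_nm = grid_nm
        self.alpha = alpha

    def fit(self, X, y=None):
        trace = X if isinstance(X, ACFTrace) else ACFTrace(*X)
        grid = (default_diameter_grid() if self.grid_nm is None
                else np.asarray(self.grid_nm, dtype=float))
        g1 = np.sqrt(np.clip(trace.g2m1, 0.0, None) / trace.beta)
        if g1.max() < 1e-6:
            raise FeatureNotFoundError("zero-signal trace: nothing to invert")

        D = np.array([diffusion_from_diameter(d, trace.temperature_K,
                                              trace.viscosity_Pa_s) for d in grid])
        A = np.exp(-np.outer(trace.lags_s, trace.q_per_m ** 2 * D))

        if self.alpha is None:
            alpha = _l_curve_alpha(A, g1)
        else:
            alpha = self.alpha
            if alpha == 0:
                cond = np.linalg.cond(A)
                if cond > 1e10:
                    warnings.warn(
                        f"dictionary condition number {cond:.2e}: unregularised "
                        "inversion is ill-posed, consider alpha > 0", stacklevel=2)
        w = _nnls_tikhonov(A, g1, alpha)
        if w.sum() <= 0:
            raise FeatureNotFoundError("inversion returned an empty distribution")
        self.alpha_ = float(alpha)
        self.distribution_ = SizeDistribution(grid, w)
        return self


def _nnls_tikhonov(A: np.ndarray, b: np.ndarray, alpha: float) -> np.ndarray:
    n = A.shape[1]
    if alpha > 0:
        A_aug = np.vstack([A, np.sqrt(alpha) * np.eye(n)])
        b_aug = np.concatenate([b, np.zeros(n)])
    else:
        A_aug, b_aug = A, b
    w, _ = nnls(A_aug, b_aug)
    return w


def _l_curve_alpha(A: np.ndarray, b: np.ndarray) -> float:
    """Pick alpha at the corner of the (log residual, log norm) L-curve."""
    alphas = np.geomspace(1e-6, 1e0, 13)
    rho, eta = [], []
    for a in alphas:
        w = _nnls_tikhonov(A, b, a)
        rho.append(np.log(np.linalg.norm(A @ w - b) + 1e-300))
        eta.append(np.log(np.linalg.norm(w) + 1e-300))
    rho, eta = np.array(rho), np.array(eta)
    # discrete curvature of the parametric curve (rho, eta)
    d1r, d1e = np.gradient(rho), np.gradient(eta)
    d2r, d2e = np.gradient(d1r), np.gradient(d1e)
    denom = (d1r ** 2 + d1e ** 2) ** 1.5 + 1e-300
    curvature = (d1r * d2e - d2r * d1e) / denom
    return float(alphas[int(np.argmax(curvature))])


def invert_distribution(trace: ACFTrace, grid_nm=None,
                        alpha: float | None = None) -> SizeDistribution:
    """Functional wrapper over :class:`DistributionInverter`."""
    return DistributionInverter(grid_nm=grid_nm, alpha=alpha).fit(trace).distribution_
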