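"""Equilibrium adsorption models and their fitting.

Models
------
Langmuir            theta = c / (1/K_L + c)
Sips (Langmuir-     theta = c^n / (1/K + c^n),  heterogeneity index
Freundlich)                                     0 < n <= 1
BET (multilayer)    Gamma = q1 K_L c / ((1 - K_ml c)(1 + (K_L - K_ml) c))

Occupancy maps to mass coverage through the site density Q and the
adsorbate molar mass m_a:  Gamma = m_a Q theta.

The fitters are scikit-learn estimators (``fit``/``predict``, fitted
attributes with trailing underscores) so they compose with sklearn
pipelines and model selection; :func:`fit_isotherm` is a thin functional
wrapper over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import AVOGADRO_PER_MOL
from .exceptions import ConvergenceError, DomainError, ValidationError

__all__ = [
    "IsothermSeries", "SipsFit", "BETFit",
    "langmuir_theta", "sips_theta", "coverage_from_theta", "bet_coverage",
    "LangmuirIsotherm", "SipsIsotherm", "BETIsotherm",
    "fit_isotherm", "half_saturation", "confidence_intervals",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class IsothermSeries:
    """Equilibrium concentration vs adsorption response.

    ``response_kind`` is one of ``mass_coverage`` (ng/cm^2),
    ``volume_coverage`` (nm^3/nm^2, i.e. nm of planar-equivalent film) or
    ``occupancy`` (dimensionless theta).
    """

    conc: np.ndarray
    response: np.ndarray
    conc_unit: str = "mol/L"
    response_kind: str = "mass_coverage"
    sigma: np.ndarray | None = None
    source: str | None = None

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.conc.shape != self.response.shape:
            raise ValidationError("conc and response differ in length")
        if np.any(self.conc < 0) or np.any(np.diff(self.conc) <= 0):
            raise ValidationError("conc must be non-negative and strictly increasing")
        if np.any(self.response < 0):
            raise ValidationError("response must be non-negative")
        if self.response_kind not in ("mass_coverage", "volume_coverage", "occupancy"):
            raise ValidationError(f"unknown response_kind {self.response_kind!r}")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.conc.shape or np.any(self.sigma <= 0):
                raise ValidationError("sigma must be positive, same length as conc")


@dataclass(frozen=True)
class SipsFit:
    """Sips (or Langmuir, n_het=1) fit result.

    ``K`` has units of (conc unit)^-n_het; ``gamma_sat = m_a Q`` is the
    saturation response; ``Q`` (sites per nm^2) is derived when ``m_a``
    (g/mol) is supplied.
    """

    K: float
    n_het: float
    gamma_sat: float
    m_a: float | None = None
    stderr: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None
    aic: float = np.nan
    rss: float = np.nan
    dof: int = 0

    @property
    def Q_per_nm2(self) -> float | None:
        if self.m_a is None:
            return None
        # gamma_sat ng/cm^2 -> molecules/nm^2
        return self.gamma_sat * 1e-9 / self.m_a * AVOGADRO_PER_MOL * 1e-14


@dataclass(frozen=True)
class BETFit:
    """BET fit result; valid only while K_ml * conc < 1."""

    q1: float
    K_L: float
    K_ml: float
    stderr: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None
    aic: float = np.nan
    rss: float = np.nan
    dof: int = 0


def confidence_intervals(fit, level: float = 0.95) -> dict:
    """Student-t Wald intervals for every fitted parameter.

    The residual variance is estimated from the fit, so the interval
    half-width is t_{1-(1-level)/2, dof} * stderr rather than a normal
    quantile.
    """
    if fit.dof < 1:
        raise ValidationError("fit has no residual degrees of freedom")
    tq = stats.t.ppf(0.5 + level / 2.0, fit.dof)
    names = ("q1", "K_L", "K_ml") if isinstance(fit, BETFit) else (
        "K", "n_het", "gamma_sat")
    out = {}
    for name in names:
        centre = getattr(fit, name if name != "gamma_sat" else "gamma_sat")
        se = fit.stderr.get(name, np.nan)
        out[name] = (centre - tq * se, centre + tq * se)
    return out


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def langmuir_theta(conc, K_L: float):
    """Langmuir occupancy theta = c / (1/K_L + c)."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValidationError("concentration must be non-negative")
    if K_L <= 0:
        raise ValidationError("K_L must be positive")
    return conc / (1.0 / K_L + conc)


def sips_theta(conc, K: float, n_het: float, *, allow_hill: bool = False):
    """Sips occupancy theta = c^n / (1/K + c^n).

    The heterogeneity index is restricted to (0, 1] — an inhomogeneous
    surface broadens, never sharpens, the isotherm.  ``allow_hill=True``
    lifts the cap for cooperative (Hill-type) use.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValidationError("concentration must be non-negative")
    if K <= 0:
        raise ValidationError("K must be positive")
    if n_het <= 0 or (n_het > 1 and not allow_hill):
        raise ValidationError("heterogeneity index must satisfy 0 < n <= 1")
    cn = np.power(conc, n_het)
    return cn / (1.0 / K + cn)


def coverage_from_theta(theta, Q_per_nm2: float, m_a_g_mol: float):
    """Mass coverage Gamma = m_a Q theta in ng/cm^2.

    Q is the site density in molecules/nm^2, m_a the adsorbate molar mass.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or Q_per_nm2 < 0 or m_a_g_mol < 0:
        raise ValidationError("inputs must be non-negative")
    # molecules/nm^2 -> mol/cm^2 -> g/cm^2 -> ng/cm^2
    return theta * Q_per_nm2 * 1e14 / AVOGADRO_PER_MOL * m_a_g_mol * 1e9


def bet_coverage(conc, q1: float, K_L: float, K_ml: float):
    """BET multilayer coverage (same response unit as q1).

    Diverges as K_ml*c -> 1 (a type-II isotherm has no saturation);
    concentrations at or beyond the divergence raise :class:`DomainError`.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValidationError("concentration must be non-negative")
    if q1 <= 0 or K_L <= 0 or K_ml < 0:
        raise ValidationError("q1, K_L must be positive and K_ml >= 0")
    if K_L <= K_ml:
        raise ValidationError("first-layer affinity K_L must exceed K_ml")
    if np.any(K_ml * conc >= 1.0):
        raise DomainError(
            "BET model diverges at K_ml*conc >= 1 (no multilayer saturation)")
    return q1 * K_L * conc / ((1.0 - K_ml * conc) * (1.0 + (K_L - K_ml) * conc))


def half_saturation(fit: SipsFit) -> float:
    """Concentration at theta = 0.5:  K^(-1/n_het)."""
    return fit.K ** (-1.0 / fit.n_het)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _as_conc(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValidationError("X must be a 1-d concentration array or (n, 1)")
    return X


class _IsothermEstimator(RegressorMixin, BaseEstimator):
    """Shared multi-start weighted-least-squares machinery.

    Subclasses define the parameter names, bounds, model function and
    start-point generator.  K-type parameters are initialised on a log
    grid spanning the data range because affinities span decades.
    """

    _param_names: tuple[str, ...] = ()

    def __init__(self, n_starts: int = 5, random_state: int = 0):
        self.n_starts = n_starts
        self.random_state = random_state

    # subclass API ---------------------------------------------------------
    def _model(self, conc, params):  # pragma: no cover - abstract
        raise NotImplementedError

    def _bounds(self, conc, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def _starts(self, conc, y, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    # ----------------------------------------------------------------------
    def fit(self, X, y, sample_weight=None):
        conc = _as_conc(X)
        y = np.asarray(y, dtype=float)
        if conc.shape != y.shape:
            raise ValidationError("X and y differ in length")
        k = len(self._param_names)
        if y.size < k + 2:
            raise ValidationError(
                f"need at least {k + 2} points to fit {k} parameters")
        w = np.ones_like(y) if sample_weight is None else np.sqrt(
            np.asarray(sample_weight, dtype=float))

        lo, hi = self._bounds(conc, y)
        rng = np.random.default_rng(self.random_state)

        def resid(p):
            return w * (self._model(conc, p) - y)

        best = None
        for p0 in self._starts(conc, y, rng):
            p0 = np.clip(p0, lo, hi)
            try:
                sol = least_squares(resid, p0, bounds=(lo, hi),
                                    xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except (ValueError, FloatingPointError):
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise ConvergenceError("all isotherm fit starts failed")

        n = y.size
        rss = float(2 * best.cost)
        dof = max(n - k, 1)
        J = best.jac
        try:
            cov = np.linalg.inv(J.T @ J) * rss / dof
            stderr = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
            stderr = np.full(k, np.nan)

        self.params_ = dict(zip(self._param_names, best.x))
        self.stderr_ = dict(zip(self._param_names, stderr))
        self.covariance_ = cov
        self.rss_ = rss
        self.dof_ = dof
        self.aic_ = n * np.log(max(rss, 1e-300) / n) + 2 * k
        self.residuals_ = resid(best.x)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        conc = _as_conc(X)
        p = np.array([self.params_[name] for name in self._param_names])
        return self._model(conc, p)


class LangmuirIsotherm(_IsothermEstimator):
    """Monolayer Langmuir fit: parameters (K_L, gamma_sat)."""

    _param_names = ("K_L", "gamma_sat")

    def _model(self, conc, p):
        K_L, gamma_sat = p
        return gamma_sat * conc / (1.0 / K_L + conc)

    def _bounds(self, conc, y):
        cmax = conc.max()
        ymax = max(y.max(), 1e-12)
        return (np.array([1e-12, 1e-12]),
                np.array([1e12 / max(cmax, 1e-12), 1e3 * ymax]))

    def _starts(self, conc, y, rng):
        cpos = conc[conc > 0]
        ymax = max(y.max(), 1e-12)
        for logK in np.linspace(np.log10(1 / cpos.max()) - 1,
                                np.log10(1 / cpos.min()) + 1, self.n_starts):
            yield np.array([10.0 ** logK, ymax])


class SipsIsotherm(_IsothermEstimator):
    """Sips / Langmuir-Freundlich fit: parameters (K, n_het, gamma_sat)."""

    _param_names = ("K", "n_het", "gamma_sat")

    def __init__(self, n_starts: int = 5, random_state: int = 0,
                 allow_hill: bool = False):
        super().__init__(n_starts=n_starts, random_state=random_state)
        self.allow_hill = allow_hill

    def _model(self, conc, p):
        K, n, gamma_sat = p
        cn = np.power(np.clip(conc, 0, None), n)
        return gamma_sat * cn / (1.0 / K + cn)

    def _bounds(self, conc, y):
        ymax = max(y.max(), 1e-12)
        n_hi = 4.0 if self.allow_hill else 1.0
        return (np.array([1e-12, 0.05, 1e-12]),
                np.array([1e12, n_hi, 1e3 * ymax]))

    def _starts(self, conc, y, rng):
        cpos = conc[conc > 0]
        ymax = max(y.max(), 1e-12)
        logs = np.linspace(np.log10(1 / cpos.max()) - 1,
                           np.log10(1 / cpos.min()) + 1, self.n_starts)
        ns = np.linspace(0.5, 1.0, self.n_starts)
        for logK, n0 in zip(logs, ns):
            yield np.array([10.0 ** logK, n0, ymax])


class BETIsotherm(_IsothermEstimator):
    """BET multilayer fit: parameters (q1, K_L, K_ml)."""

    _param_names = ("q1", "K_L", "K_ml")

    def _model(self, conc, p):
        q1, K_L, K_ml = p
        denom = (1.0 - K_ml * conc) * (1.0 + (K_L - K_ml) * conc)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = q1 * K_L * conc / denom
        return np.where(K_ml * conc < 1.0, out, 1e6 * (1 + q1))

    def _bounds(self, conc, y):
        cmax = max(conc.max(), 1e-12)
        ymax = max(y.max(), 1e-12)
        # K_ml capped below 1/cmax: the data must lie inside the domain
        return (np.array([1e-12, 1e-12, 0.0]),
                np.array([1e3 * ymax, 1e12, (1.0 - 1e-9) / cmax]))

    def _starts(self, conc, y, rng):
        cpos = conc[conc > 0]
        ymax = max(y.max(), 1e-12)
        logs = np.linspace(np.log10(1 / cpos.max()), np.log10(1 / cpos.min()) + 2,
                           self.n_starts)
        kml_fracs = np.linspace(0.0, 0.9, self.n_starts)
        for logK, f in zip(logs, kml_fracs):
            yield np.array([0.5 * ymax, 10.0 ** logK, f / cpos.max()])


_MODELS = {"langmuir": LangmuirIsotherm, "sips": SipsIsotherm, "bet": BETIsotherm}


def fit_isotherm(series: IsothermSeries, model: str = "sips",
                 weights=None, m_a: float | None = None,
                 random_state: int = 0):
    """Fit one adsorption model to a series; returns SipsFit or BETFit.

    ``weights`` are least-squares weights (e.g. 1/sigma^2); if the series
    carries per-point sigma and weights is None, 1/sigma^2 is used.
    Langmuir results are reported as a SipsFit with n_het = 1.
    """
    if model not in _MODELS:
        raise ValidationError(f"unknown model {model!r}; choose from {sorted(_MODELS)}")
    if weights is None and series.sigma is not None:
        weights = 1.0 / series.sigma ** 2
    est = _MODELS[model](random_state=random_state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est.fit(series.conc, series.response, sample_weight=weights)
    p, s = est.params_, est.stderr_
    if model == "bet":
        return BETFit(q1=p["q1"], K_L=p["K_L"], K_ml=p["K_ml"], stderr=s,
                      covariance=est.covariance_, aic=est.aic_, rss=est.rss_,
                      dof=est.dof_)
    if model == "langmuir":
        return SipsFit(K=p["K_L"], n_het=1.0, gamma_sat=p["gamma_sat"], m_a=m_a,
                       stderr={"K": s["K_L"], "gamma_sat": s["gamma_sat"]},
                       covariance=est.covariance_, aic=est.aic_, rss=est.rss_,
                       dof=est.dof_)
    return SipsFit(K=p["K"], n_het=p["n_het"], gamma_sat=p["gamma_sat"], m_a=m_a,
                   stderr=s, covariance=est.covariance_, aic=est.aic_, rss=est.rss_,
                   dof=est.dof_)
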