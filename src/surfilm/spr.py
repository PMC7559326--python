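"""Surface plasmon resonance optics in the Kretschmann configuration.

The sensor is modelled as a stack of homogeneous optical layers
(prism | gold | silica | adlayer | buffer).  p-polarised intensity
reflectivity is computed with the Abelès transfer-matrix method; the
resonance-minimum and total-internal-reflection (TIR) angles are located
with sub-gridpoint interpolation; an adsorbed-layer thickness is fitted
by least squares against an observed angle scan; and dry surface
coverage is obtained from the optical thickness with the De Feijter
relation

    Gamma = D0 / (dn/dC),     D0 = d (n - n0),

where d is the fitted layer thickness, n its (fixed) refractive index,
n0 the buffer index and dn/dC the refractive-index increment of the
adsorbate, itself measurable from the TIR-angle shift of a bulk
solution of known concentration:  dn/dC = d(theta_TIR) / (G C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import constants as C
from .exceptions import (ConvergenceError, FeatureNotFoundError,
                         ValidationError)

__all__ = [
    "OpticalLayer", "LayerStack", "AngleScan", "Sensogram",
    "InstrumentConstants", "CoverageResult", "PlateauResult",
    "default_stack", "with_adlayer", "reflectivity_scan",
    "locate_tir_angle", "locate_spr_minimum", "fit_layer_thickness",
    "dndc_from_tir_shift", "defeijter_coverage", "extract_plateaus",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalLayer:
    """One homogeneous layer: complex index and thickness in nm.

    ``thickness_nm=None`` flags a semi-infinite layer (only valid for the
    first and last layer of a stack).
    """

    name: str
    n_complex: complex
    thickness_nm: float | None = None

    def __post_init__(self):
        if self.thickness_nm is not None and self.thickness_nm < 0:
            raise ValidationError(
                f"layer {self.name!r}: negative thickness {self.thickness_nm}"
            )

    @property
    def semi_infinite(self) -> bool:
        return self.thickness_nm is None


@dataclass(frozen=True)
class LayerStack:
    """Ordered layers, prism first, probed medium last."""

    layers: tuple[OpticalLayer, ...]
    wavelength_nm: float = 670.0

    def __post_init__(self):
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        if len(layers) < 2:
            raise ValidationError("a stack needs at least two layers")
        if not (layers[0].semi_infinite and layers[-1].semi_infinite):
            raise ValidationError("first and last layers must be semi-infinite")
        for lay in layers[1:-1]:
            if lay.semi_infinite:
                raise ValidationError(
                    f"internal layer {lay.name!r} cannot be semi-infinite")
        if self.wavelength_nm <= 0:
            raise ValidationError("wavelength must be positive")


@dataclass
class AngleScan:
    """Reflectivity versus internal incidence angle (degrees)."""

    angles_deg: np.ndarray
    reflectivity: np.ndarray

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.reflectivity = np.asarray(self.reflectivity, dtype=float)
        if self.angles_deg.shape != self.reflectivity.shape:
            raise ValidationError("angle and reflectivity arrays differ in length")
        if self.angles_deg.size < 3:
            raise ValidationError("scan needs at least 3 points")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValidationError("angles must be strictly increasing")
        if self.reflectivity.min() < -1e-9 or self.reflectivity.max() > 1.5:
            raise ValidationError("reflectivity outside physical range")


@dataclass
class Sensogram:
    """Kinetic-titration time series of the two tracked angles."""

    time_s: np.ndarray
    min_angle_deg: np.ndarray
    tir_angle_deg: np.ndarray
    # (start_s, end_s, label, concentration)
    injection_marks: list[tuple[float, float, str, float]] = field(default_factory=list)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.min_angle_deg = np.asarray(self.min_angle_deg, dtype=float)
        self.tir_angle_deg = np.asarray(self.tir_angle_deg, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValidationError("time must be strictly increasing")
        if not (self.time_s.shape == self.min_angle_deg.shape == self.tir_angle_deg.shape):
            raise ValidationError("sensogram channels differ in length")
        t0, t1 = self.time_s[0], self.time_s[-1]
        for start, end, label, _conc in self.injection_marks:
            if not (t0 <= start < end <= t1):
                raise ValidationError(f"injection mark {label!r} outside time range")


@dataclass(frozen=True)
class InstrumentConstants:
    """TIR sensitivity factors G (deg/RIU) keyed by wavelength, and n0."""

    G_deg_per_RIU: dict = field(
        default_factory=lambda: dict(C.G_FACTOR_DEG_PER_RIU))
    n_buffer: float = C.N_BUFFER

    def __post_init__(self):
        if any(g <= 0 for g in self.G_deg_per_RIU.values()):
            raise ValidationError("G factors must be positive")

    def G(self, wavelength_nm: float) -> float:
        try:
            return self.G_deg_per_RIU[float(wavelength_nm)]
        except KeyError:
            raise ValidationError(
                f"no G factor configured for wavelength {wavelength_nm} nm"
            ) from None


@dataclass(frozen=True)
class CoverageResult:
    """De Feijter output: coverage, the thickness that produced it, D0, dn/dC."""

    gamma_ng_cm2: float
    d_fit_nm: float
    optical_thickness_nm: float
    dndc_cm3_g: float


@dataclass(frozen=True)
class PlateauResult:
    label: str
    concentration: float
    plateau_angle_deg: float
    stable: bool


# ---------------------------------------------------------------------------
# stack construction helpers
# ---------------------------------------------------------------------------

def default_stack(wavelength_nm: float = 670.0, *,
                  adlayer_n: float | None = None,
                  adlayer_d_nm: float = 0.0) -> LayerStack:
    """Kretschmann default: BK7 prism / 50 nm gold / 10 nm silica / buffer.

    If ``adlayer_n`` is given an adlayer of thickness ``adlayer_d_nm`` is
    inserted between the silica and the buffer.
    """
    try:
        n_gold = C.GOLD_INDEX[float(wavelength_nm)]
    except KeyError:
        raise ValidationError(
            f"no gold index configured for {wavelength_nm} nm") from None
    layers = [
        OpticalLayer("prism", C.N_BK7),
        OpticalLayer("gold", n_gold, C.GOLD_THICKNESS_NM),
        OpticalLayer("silica", C.N_SILICA, C.SILICA_THICKNESS_NM),
    ]
    if adlayer_n is not None:
        layers.append(OpticalLayer("adlayer", adlayer_n, adlayer_d_nm))
    layers.append(OpticalLayer("buffer", C.N_BUFFER))
    return LayerStack(tuple(layers), wavelength_nm)


def with_adlayer(stack: LayerStack, n: float, d_nm: float) -> LayerStack:
    """Return a copy of *stack* with an adlayer of index n and thickness d
    inserted (or replaced) just before the final medium."""
    layers = list(stack.layers)
    if layers[-2].name == "adlayer":
        layers[-2] = OpticalLayer("adlayer", n, d_nm)
    else:
        layers.insert(-1, OpticalLayer("adlayer", n, d_nm))
    return LayerStack(tuple(layers), stack.wavelength_nm)


# ---------------------------------------------------------------------------
# transfer-matrix forward model
# ---------------------------------------------------------------------------

def _kz(n: complex, k0: float, kx: np.ndarray) -> np.ndarray:
    # principal sqrt: decaying evanescent waves get Im(kz) >= 0
    return np.sqrt((k0 * n) ** 2 - kx ** 2 + 0j)


def reflectivity_scan(stack: LayerStack, angles_deg) -> AngleScan:
    """p-polarised intensity reflectivity of *stack* at each internal angle.

    Uses the 2x2 characteristic-matrix (Abelès) formulation with the TM
    admittance q_j = kz_j / n_j^2.
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    if np.any((angles_deg <= 0) | (angles_deg >= 90)):
        raise ValidationError("angles must lie in (0, 90) degrees")

    k0 = 2.0 * np.pi / stack.wavelength_nm  # 1/nm
    n_first = stack.layers[0].n_complex
    theta = np.deg2rad(angles_deg)
    kx = k0 * np.real(n_first) * np.sin(theta)

    q_first = _kz(n_first, k0, kx) / n_first ** 2
    q_last = _kz(stack.layers[-1].n_complex, k0, kx) / stack.layers[-1].n_complex ** 2

    # running product of characteristic matrices, vectorised over angle
    m00 = np.ones_like(kx, dtype=complex)
    m01 = np.zeros_like(m00)
    m10 = np.zeros_like(m00)
    m11 = np.ones_like(m00)
    for lay in stack.layers[1:-1]:
        kz = _kz(lay.n_complex, k0, kx)
        q = kz / lay.n_complex ** 2
        delta = kz * lay.thickness_nm
        cd, sd = np.cos(delta), np.sin(delta)
        a00, a01 = cd, -1j * sd / q
        a10, a11 = -1j * q * sd, cd
        m00, m01, m10, m11 = (m00 * a00 + m01 * a10,
                              m00 * a01 + m01 * a11,
                              m10 * a00 + m11 * a10,
                              m10 * a01 + m11 * a11)

    num = q_first * (m00 + m01 * q_last) - (m10 + m11 * q_last)
    den = q_first * (m00 + m01 * q_last) + (m10 + m11 * q_last)
    r = num / den
    R = np.abs(r) ** 2
    return AngleScan(angles_deg, np.clip(R, 0.0, None))


# ---------------------------------------------------------------------------
# angle-feature location
# ---------------------------------------------------------------------------

def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> float:
    """Vertex abscissa of the parabola through three points."""
    denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
    a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
    b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0])
         + x[0] ** 2 * (y[1] - y[2])) / denom
    if a == 0:
        return float(x[1])
    return float(-b / (2 * a))


def locate_tir_angle(scan: AngleScan) -> float:
    """Critical-angle position: the maximum slope of the reflectivity rise,
    refined to sub-gridpoint precision with a local quadratic."""
    r = scan.reflectivity
    if np.ptp(r) < 1e-9:
        raise FeatureNotFoundError("scan is flat: no TIR shoulder present")
    deriv = np.gradient(r, scan.angles_deg)
    i = int(np.argmax(deriv))
    if deriv[i] <= 0:
        raise FeatureNotFoundError("no rising edge found in scan")
    if 0 < i < len(r) - 1:
        return _parabolic_vertex(scan.angles_deg[i - 1:i + 2], deriv[i - 1:i + 2])
    return float(scan.angles_deg[i])


def locate_spr_minimum(scan: AngleScan) -> float:
    """Resonance-dip position via 3-point parabolic interpolation.

    A minimum sitting on a grid edge is returned as-is with a warning.
    """
    r = scan.reflectivity
    if np.ptp(r) < 1e-12:
        warnings.warn("scan is flat; returning first angle", stacklevel=2)
        return float(scan.angles_deg[0])
    i = int(np.argmin(r))
    if i == 0 or i == len(r) - 1:
        warnings.warn("reflectivity minimum at grid boundary", stacklevel=2)
        return float(scan.angles_deg[i])
    return _parabolic_vertex(scan.angles_deg[i - 1:i + 2], r[i - 1:i + 2])


# ---------------------------------------------------------------------------
# thickness fitting and coverage
# ---------------------------------------------------------------------------

def fit_layer_thickness(observed: AngleScan, stack: LayerStack,
                        adlayer_n: float = C.N_PROTEIN,
                        bounds: tuple[float, float] = (0.0, 100.0)):
    """Least-squares adlayer thickness reproducing an observed scan.

    All other layers are held fixed; the adlayer index is fixed at
    ``adlayer_n`` (thickness and index are degenerate in a
    single-wavelength fit).  A coarse grid search brackets the optimum,
    then a bounded scalar minimisation refines it.

    Returns (d_nm, residual) where residual is the root-mean-square
    reflectivity misfit at the optimum.
    """
    lo, hi = bounds
    angles = observed.angles_deg
    target = observed.reflectivity

    def sse(d: float) -> float:
        model = reflectivity_scan(with_adlayer(stack, adlayer_n, d), angles)
        return float(np.sum((model.reflectivity - target) ** 2))

    grid = np.linspace(lo, hi, 201)
    vals = np.array([sse(d) for d in grid])
    i = int(np.argmin(vals))
    if i == len(grid) - 1 and vals[-1] < vals[-2]:
        raise ConvergenceError(
            "no thickness minimum bracketed inside bounds",
            diagnostics={"bounds": bounds, "edge_sse": float(vals[-1])})
    blo = grid[max(i - 1, 0)]
    bhi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(sse, bounds=(blo, bhi), method="bounded",
                          options={"xatol": 1e-7})
    if not res.success:
        raise ConvergenceError("thickness refinement failed",
                               diagnostics={"message": res.message})
    d = float(res.x)
    rms = float(np.sqrt(res.fun / angles.size))
    return d, rms


def dndc_from_tir_shift(delta_tir_deg: float,
                        constants: InstrumentConstants,
                        wavelength_nm: float,
                        conc_g_cm3: float) -> float:
    """Refractive-index increment dn/dC (cm^3/g) from a bulk TIR shift."""
    if conc_g_cm3 <= 0:
        raise ValidationError("concentration must be positive")
    return delta_tir_deg / (constants.G(wavelength_nm) * conc_g_cm3)


def defeijter_coverage(d_fit_nm: float, adlayer_n: float,
                       constants: InstrumentConstants,
                       dndc_cm3_g: float) -> CoverageResult:
    """Dry surface coverage from a fitted layer thickness.

    D0 = d (n - n0) in nm; Gamma = D0 / (dn/dC) converted to ng/cm^2.
    """
    if dndc_cm3_g <= 0:
        raise ValidationError("dn/dC must be positive")
    if adlayer_n <= constants.n_buffer:
        raise ValidationError(
            "adlayer index must exceed the buffer index (coverage >= 0)")
    if d_fit_nm < 0:
        raise ValidationError("thickness must be non-negative")
    d0_nm = d_fit_nm * (adlayer_n - constants.n_buffer)
    # D0 [cm] / dndc [cm^3/g] = g/cm^2 ; x1e9 -> ng/cm^2 ; 1 nm = 1e-7 cm
    gamma = d0_nm * 1e-7 / dndc_cm3_g * 1e9
    return CoverageResult(gamma, d_fit_nm, d0_nm, dndc_cm3_g)


# ---------------------------------------------------------------------------
# sensogram plateau extraction
# ---------------------------------------------------------------------------

def extract_plateaus(sensogram: Sensogram, window_s: float = 60.0,
                     slope_tol_deg_s: float = 1e-4) -> list[PlateauResult]:
    """Post-rinse plateau angle for each injection, baseline-subtracted.

    For every injection mark the buffer phase runs from the mark's end to
    the start of the next mark (or the end of the record).  The latest
    ``window_s``-long segment whose linear-fit slope is below
    ``slope_tol_deg_s`` defines the plateau; its mean angle minus the
    pre-first-injection baseline is reported.  Segments never stabilising
    are returned flagged (``stable=False``) rather than dropped.
    """
    if not sensogram.injection_marks:
        raise ValidationError("sensogram has no injection marks")
    t = sensogram.time_s
    y = sensogram.min_angle_deg
    marks = sorted(sensogram.injection_marks, key=lambda m: m[0])

    pre = t < marks[0][0]
    baseline = float(np.mean(y[pre])) if pre.any() else float(y[0])

    results = []
    for k, (start, end, label, conc) in enumerate(marks):
        region_end = marks[k + 1][0] if k + 1 < len(marks) else t[-1]
        plateau, stable = _find_stable_window(
            t, y, end, region_end, window_s, slope_tol_deg_s)
        results.append(PlateauResult(label, conc, plateau - baseline, stable))
    return results


def _find_stable_window(t, y, t_lo, t_hi, window_s, slope_tol):
    """Scan candidate windows from the latest backwards; first stable wins."""
    step = max(window_s / 4.0, float(np.median(np.diff(t))))
    end = t_hi
    best_mean = np.nan
    while end - window_s >= t_lo:
        sel = (t >= end - window_s) & (t <= end)
        if sel.sum() >= 3:
            ts, ys = t[sel], y[sel]
            slope = np.polyfit(ts - ts[0], ys, 1)[0]
            mean = float(np.mean(ys))
            if np.isnan(best_mean):
                best_mean = mean
            if abs(slope) < slope_tol:
                return mean, True
        end -= step
    if np.isnan(best_mean):  # region shorter than the window: use it whole
        sel = (t >= t_lo) & (t <= t_hi)
        best_mean = float(np.mean(y[sel])) if sel.any() else float(y[-1])
    return best_mean, False
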