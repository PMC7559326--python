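"""Electrokinetic and diffusion-exchange transport relations.

Smoluchowski zeta potential from electrophoretic mobility (valid for
thin double layers, kappa*a >> 1) and the two-site fast-exchange
relation mapping an observed diffusion coefficient to a bound fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from . import constants as C
from .exceptions import ValidationError
from .units import mobility_to_si

__all__ = [
    "MobilityRecord", "DiffusionPair", "smoluchowski_zeta",
    "two_site_fraction_bound", "detectable_bound_fraction",
]


@dataclass(frozen=True)
class MobilityRecord:
    """Electrophoretic mobility with the medium properties needed for zeta.

    The unit must be declared explicitly; accepted spellings are
    ``um_cm/V_s`` (µm·cm per V·s, = 1e-8 m^2/(V s)) and ``m2/V_s``.
    """

    mobility: float
    unit: str = "um_cm/V_s"
    temperature_K: float = C.ROOM_TEMPERATURE_K
    viscosity_Pa_s: float = C.WATER_VISCOSITY_PA_S
    rel_permittivity: float = C.WATER_REL_PERMITTIVITY
    mobility_sd: float = 0.0

    def __post_init__(self):
        if self.viscosity_Pa_s <= 0 or self.rel_permittivity <= 0:
            raise ValidationError("viscosity and permittivity must be positive")
        mobility_to_si(0.0, self.unit)  # validate the unit spelling early

    @property
    def mobility_si(self) -> float:
        return mobility_to_si(self.mobility, self.unit)


@dataclass(frozen=True)
class DiffusionPair:
    """Observed, free and bound diffusion coefficients (m^2/s)."""

    D_obs: float
    D_free: float
    D_bound: float

    def __post_init__(self):
        if not self.D_bound < self.D_free:
            raise ValidationError("D_bound must be smaller than D_free")


def smoluchowski_zeta(rec: MobilityRecord) -> tuple[float, float]:
    """zeta = eta * mu / (eps0 * eps_r), returned in mV with its
    linearly-propagated standard deviation."""
    eps = C.VACUUM_PERMITTIVITY_F_M * rec.rel_permittivity
    scale = rec.viscosity_Pa_s / eps * 1e3  # V -> mV
    zeta = rec.mobility_si * scale
    zeta_sd = abs(mobility_to_si(rec.mobility_sd, rec.unit)) * scale
    return zeta, zeta_sd


def two_site_fraction_bound(pair: DiffusionPair) -> float:
    """Bound fraction under fast two-site exchange.

    D_obs = f_b D_bound + (1 - f_b) D_free, hence
    f_b = (D_free - D_obs) / (D_free - D_bound).  Observed values
    outside [D_bound, D_free] are clipped with a warning (measurement
    noise), never silently.
    """
    f = (pair.D_free - pair.D_obs) / (pair.D_free - pair.D_bound)
    if f < 0 or f > 1:
        warnings.warn(
            f"D_obs outside [D_bound, D_free]; clipping f_b={f:.3g} to [0, 1]",
            stacklevel=2)
        f = min(max(f, 0.0), 1.0)
    return float(f)


def detectable_bound_fraction(D_free: float, D_bound: float,
                              rel_error: float) -> float:
    """Smallest bound fraction resolvable at a relative error on D.

    The observed shift is |D_obs - D_free|/D_free = f_b (1 - D_bound/D_free);
    setting it equal to ``rel_error`` gives
    f = rel_error * D_free / (D_free - D_bound).  Bound fractions below
    this are invisible to a diffusion measurement of that precision.
    """
    if rel_error <= 0:
        raise ValidationError("relative error must be positive")
    if not D_bound < D_free:
        raise ValidationError("D_bound must be smaller than D_free")
    return rel_error * D_free / (D_free - D_bound)
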