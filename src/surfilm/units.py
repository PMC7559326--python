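"""Centralised unit conversions.

Internal conventions: thickness nm, surface coverage ng/cm^2,
bulk concentration g/cm^3 for optics, mol/L for isotherms.
Mobilities must declare their unit explicitly; nothing is inferred.
"""

from __future__ import annotations

from .exceptions import ValidationError

# Accepted mobility unit spellings -> factor to m^2/(V s)
_MOBILITY_UNITS = {
    "um_cm/V_s": 1e-8,     # µm·cm/(V·s), the unit mobilities are printed in
    "umcm/Vs": 1e-8,
    "m2/V_s": 1.0,
    "m2/Vs": 1.0,
}


def mobility_to_si(value: float, unit: str) -> float:
    """Convert an electrophoretic mobility to m^2/(V s)."""
    try:
        return value * _MOBILITY_UNITS[unit]
    except KeyError:
        raise ValidationError(
            f"unknown mobility unit {unit!r}; accepted: {sorted(_MOBILITY_UNITS)}"
        ) from None


def wt_percent_to_mol_per_L(wt_percent: float, molar_mass_g_mol: float,
                            density_g_mL: float = 1.0) -> float:
    """wt% -> mol/L assuming the stated solution density (default 1 g/mL)."""
    if molar_mass_g_mol <= 0:
        raise ValidationError("molar mass must be positive")
    grams_per_L = wt_percent * 10.0 * density_g_mL
    return grams_per_L / molar_mass_g_mol


def mg_per_mL_to_uM(mg_per_mL: float, molar_mass_g_mol: float) -> float:
    """mg/mL -> µmol/L (e.g. 2 mg/mL BSA at 66.5 kg/mol -> 30 µM)."""
    if molar_mass_g_mol <= 0:
        raise ValidationError("molar mass must be positive")
    return mg_per_mL / molar_mass_g_mol * 1e6


def uM_to_mol_per_L(uM: float) -> float:
    return uM * 1e-6


_CONC_CONVERTERS = {
    ("wt_percent", "mol/L"): lambda v, M: wt_percent_to_mol_per_L(v, M),
    ("mg/mL", "uM"): lambda v, M: mg_per_mL_to_uM(v, M),
    ("uM", "mol/L"): lambda v, M: uM_to_mol_per_L(v),
    ("mol/L", "mol/L"): lambda v, M: v,
    ("uM", "uM"): lambda v, M: v,
    ("wt_percent", "wt_percent"): lambda v, M: v,
}


def convert_concentration(value, from_unit: str, to_unit: str,
                          molar_mass_g_mol: float | None = None):
    """Convert between the concentration units the pipeline encounters."""
    key = (from_unit, to_unit)
    if key not in _CONC_CONVERTERS:
        raise ValidationError(f"no converter {from_unit!r} -> {to_unit!r}")
    return _CONC_CONVERTERS[key](value, molar_mass_g_mol)
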