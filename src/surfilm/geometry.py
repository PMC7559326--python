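"""Film-geometry corrections: the common planar-equivalent thickness.

Two measurement modes see the same adsorbed surfactant film differently:

* SPR reports the *dry* mass coverage Gamma on a flat surface; adding
  the hydration water bound to the ethoxylated head groups (six waters
  per EO group) converts it to the volume of the hydrated film, whose
  volume-to-area ratio on a plane is simply a thickness.
* DLS reports a hydrodynamic thickness Delta_r_h on a sphere of radius
  R; a film of thickness d on a surface of mean curvature H_c and
  Gaussian curvature K_c has

      V/A = d (1 + H_c d + K_c d^2 / 3),

  which for a sphere (H_c = 1/R, K_c = 1/R^2) is the exact shell volume
  per unit inner area.  Inserting d = Delta_r_h gives the
  planar-equivalent thickness the film would have on a flat surface.

After both corrections the two modes are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import AVOGADRO_PER_MOL
from .exceptions import ValidationError

__all__ = [
    "HydrationModel", "CoatedParticle", "FilmThickness",
    "hydrated_molar_volume", "spr_film_thickness", "area_per_molecule",
    "hydrodynamic_thickness", "curved_volume_per_area",
    "planar_equivalent_thickness", "merge_geometry_series",
]


@dataclass(frozen=True)
class HydrationModel:
    """Hydration bookkeeping for an ethoxylated surfactant head group.

    Defaults describe C10PEG: eight EO groups, six bound waters each,
    anhydrous molar volume 511 cm^3/mol (density close to 1) and molar
    mass 511 g/mol.
    """

    n_EO: float = 8.0
    waters_per_EO: float = 6.0
    v_water_cm3_mol: float = 18.0
    v_anhydrous_cm3_mol: float = 511.0
    molar_mass_g_mol: float = 511.0

    def __post_init__(self):
        if min(self.n_EO, self.v_water_cm3_mol, self.v_anhydrous_cm3_mol,
               self.molar_mass_g_mol) <= 0 or self.waters_per_EO < 0:
            raise ValidationError("hydration model fields must be positive")


@dataclass(frozen=True)
class CoatedParticle:
    """Protein-coated bead: core radius and hydrodynamic radii (nm)."""

    core_radius_nm: float = 20.0
    r_h0_nm: float = 22.0
    r_h_nm: float = 22.0

    def __post_init__(self):
        if self.core_radius_nm <= 0:
            raise ValidationError("core radius must be positive")
        if self.r_h_nm < self.r_h0_nm:
            raise ValidationError(
                "hydrodynamic radius below baseline: apparent film shrinkage")

    @property
    def mean_curvature_per_nm(self) -> float:
        return 1.0 / self.core_radius_nm

    @property
    def gaussian_curvature_per_nm2(self) -> float:
        return 1.0 / self.core_radius_nm ** 2


@dataclass(frozen=True)
class FilmThickness:
    """Planar-equivalent film thickness with its provenance tag."""

    value_nm: float
    source: str  # spr_hydrated | dls_curvature_corrected | dls_raw

    def __post_init__(self):
        if self.value_nm < 0:
            raise ValidationError("thickness must be non-negative")
        if self.source not in ("spr_hydrated", "dls_curvature_corrected", "dls_raw"):
            raise ValidationError(f"unknown thickness source {self.source!r}")


def hydrated_molar_volume(model: HydrationModel) -> tuple[float, float]:
    """Effective molar volume (cm^3/mol) and waters per polar head.

    v_eff = v_anhydrous + n_EO * waters_per_EO * v_water.
    Defaults give 48 waters and 1375 cm^3/mol.
    """
    waters = model.n_EO * model.waters_per_EO
    return model.v_anhydrous_cm3_mol + waters * model.v_water_cm3_mol, waters


def spr_film_thickness(gamma_ng_cm2: float, model: HydrationModel) -> FilmThickness:
    """Hydrated-film thickness (nm) from a dry SPR coverage.

    thickness = (Gamma / M) * v_eff since on a plane V/A is the
    thickness; Gamma ng/cm^2 with v_eff cm^3/mol gives cm, converted to nm.
    """
    if gamma_ng_cm2 < 0:
        raise ValidationError("coverage must be non-negative")
    v_eff, _ = hydrated_molar_volume(model)
    thickness_cm = gamma_ng_cm2 * 1e-9 / model.molar_mass_g_mol * v_eff
    return FilmThickness(thickness_cm * 1e7, "spr_hydrated")


def area_per_molecule(gamma_ng_cm2: float, molar_mass_g_mol: float) -> float:
    """Average area per adsorbed molecule (A^2) at coverage Gamma."""
    if gamma_ng_cm2 <= 0:
        raise ValidationError("coverage must be positive")
    area_cm2 = molar_mass_g_mol / (gamma_ng_cm2 * 1e-9 * AVOGADRO_PER_MOL)
    return area_cm2 * 1e16  # cm^2 -> A^2


def hydrodynamic_thickness(particle: CoatedParticle) -> float:
    """Delta_r_h = r_h - r_h0 (nm); negative growth is rejected upstream."""
    return particle.r_h_nm - particle.r_h0_nm


def curved_volume_per_area(d_nm: float, H_c_per_nm: float,
                           K_c_per_nm2: float) -> float:
    """V/A = d (1 + H_c d + K_c d^2 / 3) for a film on a curved surface.

    Exact for spheres; reduces to d on a plane (H_c = K_c = 0).
    """
    if d_nm < 0:
        raise ValidationError("thickness must be non-negative")
    return d_nm * (1.0 + H_c_per_nm * d_nm + K_c_per_nm2 * d_nm ** 2 / 3.0)


def planar_equivalent_thickness(delta_rh_nm: float, R_nm: float) -> FilmThickness:
    """Curvature-corrected planar-equivalent thickness of a DLS film.

    Specialises the V/A relation to a sphere of radius R with
    d = Delta_r_h; always >= Delta_r_h, approaching it as R -> inf.
    """
    if delta_rh_nm < 0:
        raise ValidationError("hydrodynamic thickness must be non-negative")
    if R_nm <= 0:
        raise ValidationError("particle radius must be positive")
    value = curved_volume_per_area(delta_rh_nm, 1.0 / R_nm, 1.0 / R_nm ** 2)
    return FilmThickness(value, "dls_curvature_corrected")


def merge_geometry_series(spr: pd.DataFrame, dls: pd.DataFrame,
                          conc_col: str = "conc") -> tuple[pd.DataFrame, float]:
    """Merge SPR and DLS thickness series into one volume-coverage series.

    Both frames need columns (conc, thickness_nm, source) in a shared
    concentration unit.  Returns the combined frame sorted by
    concentration plus the mean |SPR - DLS| discrepancy over the
    overlapping concentration range (DLS interpolated onto the SPR
    points); NaN when the ranges are disjoint (a warning is issued and
    the series are still merged).
    """
    frames = [df for df in (spr, dls) if df is not None and len(df)]
    if not frames:
        raise ValidationError("nothing to merge")
    merged = (pd.concat(frames, ignore_index=True)
              .sort_values(conc_col, kind="stable").reset_index(drop=True))

    discrepancy = np.nan
    if spr is not None and dls is not None and len(spr) and len(dls):
        lo = max(spr[conc_col].min(), dls[conc_col].min())
        hi = min(spr[conc_col].max(), dls[conc_col].max())
        if lo <= hi:
            s = spr[(spr[conc_col] >= lo) & (spr[conc_col] <= hi)]
            if len(s):
                dls_sorted = dls.sort_values(conc_col)
                interp = np.interp(s[conc_col], dls_sorted[conc_col],
                                   dls_sorted["thickness_nm"])
                discrepancy = float(np.mean(np.abs(s["thickness_nm"].to_numpy()
                                                   - interp)))
        else:
            warnings.warn("SPR and DLS concentration ranges do not overlap",
                          stacklevel=2)
    return merged, discrepancy
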