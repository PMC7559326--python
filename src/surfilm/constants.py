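"""Physical constants and instrument defaults used throughout the package.

Every report emitted by the pipeline echoes this table so that derived
quantities (e.g. the −31 mV-class ζ-potential checks) are reproducible.
"""

from __future__ import annotations

# Fundamental constants (SI)
BOLTZMANN_J_K = 1.380649e-23
AVOGADRO_PER_MOL = 6.02214076e23
VACUUM_PERMITTIVITY_F_M = 8.8541878128e-12

# Water at 25 °C
WATER_VISCOSITY_PA_S = 8.9e-4
WATER_REL_PERMITTIVITY = 78.4
ROOM_TEMPERATURE_K = 298.15

# SPR instrument: TIR-angle sensitivity factor G (degrees per RIU),
# one entry per laser wavelength (nm).
G_FACTOR_DEG_PER_RIU = {670.0: 86.3, 785.0: 87.5}

# Kretschmann stack optical defaults.  The instrument class uses a BK7
# prism, a thin gold film and a 10 nm silica top coat; complex gold
# indices are literature values at the two laser lines.
N_BK7 = 1.52
N_SILICA = 1.46
N_BUFFER = 1.334
N_PROTEIN = 1.52       # refractive index used for the BSA adlayer
N_SURFACTANT = 1.45    # refractive index used for the surfactant adlayer
GOLD_INDEX = {670.0: 0.14 + 3.7j, 785.0: 0.17 + 4.9j}
GOLD_THICKNESS_NM = 50.0
SILICA_THICKNESS_NM = 10.0

# SPR acquisition angle range (degrees)
ANGLE_MIN_DEG = 50.0
ANGLE_MAX_DEG = 77.5
ANGLE_STEP_DEG = 0.01

# DLS backscatter optics (configurable; typical of the instrument class)
DLS_SCATTERING_ANGLE_DEG = 173.0
DLS_WAVELENGTH_NM = 633.0
DLS_MEDIUM_INDEX = 1.33

# Molar masses (g/mol)
MOLAR_MASS_C10PEG = 511.0
MOLAR_MASS_BSA = 66_500.0


def constants_table() -> dict:
    """Return the full constants table for embedding in reports."""
    return {
        "k_B_J_K": BOLTZMANN_J_K,
        "N_A_per_mol": AVOGADRO_PER_MOL,
        "eps0_F_m": VACUUM_PERMITTIVITY_F_M,
        "water_viscosity_Pa_s": WATER_VISCOSITY_PA_S,
        "water_rel_permittivity": WATER_REL_PERMITTIVITY,
        "temperature_K": ROOM_TEMPERATURE_K,
        "G_deg_per_RIU": {str(k): v for k, v in G_FACTOR_DEG_PER_RIU.items()},
        "n_prism": N_BK7,
        "n_silica": N_SILICA,
        "n_buffer": N_BUFFER,
        "n_protein": N_PROTEIN,
        "n_surfactant": N_SURFACTANT,
        "gold_index": {str(k): [v.real, v.imag] for k, v in GOLD_INDEX.items()},
        "gold_thickness_nm": GOLD_THICKNESS_NM,
        "silica_thickness_nm": SILICA_THICKNESS_NM,
        "dls_scattering_angle_deg": DLS_SCATTERING_ANGLE_DEG,
        "dls_wavelength_nm": DLS_WAVELENGTH_NM,
        "dls_medium_index": DLS_MEDIUM_INDEX,
        "molar_mass_C10PEG_g_mol": MOLAR_MASS_C10PEG,
        "molar_mass_BSA_g_mol": MOLAR_MASS_BSA,
    }
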