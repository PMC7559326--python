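"""Seeded synthetic-data generators with known ground truth.

Every generator draws from ``numpy.random.default_rng(seed)`` and
returns (or writes) the same structures the analysis modules consume,
together with a ground-truth record so recovery tests never peek at the
implementation under test.

The default scenario mirrors the study conditions the pipeline was
built around: 30 nm silica beads, a 7 nm protein monolayer (coated
diameter 44 nm, curvature radius 20 nm), BSA adsorption saturating at
450 ng/cm^2 with half-saturation at 12 µM, and a non-ionic ethoxylated
surfactant whose multilayer growth follows a BET law chosen to give a
~460 ng/cm^2-class dry coverage at 2 wt% and a ~32 nm planar-equivalent
film at 9 wt%.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import constants as C
from .dls import ACFTrace, SizeDistribution, default_diameter_grid, field_acf_model, siegert
from .exceptions import ValidationError
from .geometry import HydrationModel, hydrated_molar_volume
from .isotherms import bet_coverage, sips_theta
from .spr import AngleScan, LayerStack, Sensogram, default_stack, reflectivity_scan, with_adlayer
from .units import wt_percent_to_mol_per_L

__all__ = [
    "ScenarioConfig", "gen_angle_scan", "gen_titration_sensogram",
    "gen_acf", "gen_aggregation_profile", "gen_scenario_fixture",
    "write_fixture",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth parameters and noise levels of the default scenario."""

    seed: int = 0
    # protein (BSA) adsorption truth — Sips
    sips_n: float = 0.7
    half_sat_uM: float = 12.0
    gamma_sat_ng_cm2: float = 450.0
    dndc_protein_cm3_g: float = 0.186
    # surfactant multilayer truth — BET (conc in mol/L, coverage in nm)
    bet_q1_nm: float = 12.0
    bet_K_L_M: float = 100.0
    bet_K_ml_M: float = 3.55
    dndc_surfactant_cm3_g: float = 0.131
    # particle geometry (nm)
    pristine_diameter_nm: float = 30.0
    protein_layer_nm: float = 7.0
    curvature_radius_nm: float = 20.0
    # noise levels
    scan_noise_rel: float = 0.0
    acf_noise: float = 2e-3
    sensogram_noise_deg: float = 0.0
    # electrophoretic mobilities (µm·cm/(V·s))
    mobility_pristine: float = -2.43
    mobility_pristine_sd: float = 0.04
    mobility_coated: float = -0.84
    mobility_coated_sd: float = 0.11

    @property
    def sips_K(self) -> float:
        """Average affinity in µM^-n such that theta(half_sat) = 0.5."""
        return self.half_sat_uM ** (-self.sips_n)

    @property
    def coated_diameter_nm(self) -> float:
        return self.pristine_diameter_nm + 2.0 * self.protein_layer_nm


# ---------------------------------------------------------------------------
# low-level generators
# ---------------------------------------------------------------------------

def gen_angle_scan(stack: LayerStack, d_true_nm: float, adlayer_n: float,
                   noise_rel: float = 0.0, seed: int = 0,
                   angles_deg=None) -> tuple[AngleScan, dict]:
    """Forward-model an angle scan for a given adlayer and add
    multiplicative Gaussian noise; the ground truth rides along."""
    if angles_deg is None:
        angles_deg = np.arange(C.ANGLE_MIN_DEG, C.ANGLE_MAX_DEG + 1e-9,
                               C.ANGLE_STEP_DEG)
    scan = reflectivity_scan(with_adlayer(stack, adlayer_n, d_true_nm), angles_deg)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        noisy = scan.reflectivity * (1.0 + noise_rel * rng.standard_normal(
            scan.reflectivity.shape))
        scan = AngleScan(scan.angles_deg, np.clip(noisy, 0.0, 1.49))
    truth = {"d_true_nm": d_true_nm, "adlayer_n": adlayer_n,
             "noise_rel": noise_rel, "seed": seed}
    return scan, truth


def gen_titration_sensogram(conc_steps, plateau_angles_deg,
                            baseline_s: float = 120.0,
                            inject_s: float = 300.0,
                            rinse_s: float = 300.0,
                            tau_s: float = 20.0,
                            bulk_jump_deg: float = 0.05,
                            drift_deg_s: float = 0.0,
                            noise_deg: float = 0.0,
                            dndc_cm3_g: float | None = None,
                            conc_g_cm3=None,
                            G_deg_per_RIU: float = 86.3,
                            tir0_deg: float = 61.39,
                            dt_s: float = 1.0,
                            seed: int = 0) -> tuple[Sensogram, dict]:
    """Stepwise kinetic-titration sensogram with stable post-rinse plateaus.

    Each injection drives the resonance-minimum angle exponentially
    (time constant ``tau_s``) towards its programmed plateau plus a bulk
    refractive-index transient; the rinse relaxes onto the plateau.  If
    ``dndc_cm3_g`` and per-step concentrations in g/cm^3 are supplied,
    the TIR channel steps by G * dndc * C during each injection so the
    refractive-index increment can be recovered downstream.
    """
    conc_steps = list(conc_steps)
    plateau_angles_deg = list(plateau_angles_deg)
    if len(conc_steps) != len(plateau_angles_deg):
        raise ValidationError("one plateau per concentration step required")
    n_steps = len(conc_steps)
    total = baseline_s + n_steps * (inject_s + rinse_s)
    t = np.arange(0.0, total + dt_s, dt_s)
    angle = np.zeros_like(t)
    tir = np.full_like(t, tir0_deg)
    marks = []

    prev_plateau = 0.0
    for i, (conc, plateau) in enumerate(zip(conc_steps, plateau_angles_deg)):
        start = baseline_s + i * (inject_s + rinse_s)
        end = start + inject_s
        marks.append((start, end, f"step{i + 1}", conc))
        inj = (t >= start) & (t < end)
        rinse = (t >= end) & (t < end + rinse_s + dt_s / 2)
        target = plateau + bulk_jump_deg
        angle[inj] = target + (prev_plateau - target) * np.exp(-(t[inj] - start) / tau_s)
        v_end = target + (prev_plateau - target) * np.exp(-inject_s / tau_s)
        angle[rinse] = plateau + (v_end - plateau) * np.exp(-(t[rinse] - end) / tau_s)
        angle[t >= end + rinse_s] = plateau
        if dndc_cm3_g is not None and conc_g_cm3 is not None:
            shift = G_deg_per_RIU * dndc_cm3_g * conc_g_cm3[i]
            tir[inj] = tir0_deg + shift * (1 - np.exp(-(t[inj] - start) / tau_s))
        prev_plateau = plateau

    angle += drift_deg_s * t
    if noise_deg > 0:
        rng = np.random.default_rng(seed)
        angle = angle + noise_deg * rng.standard_normal(angle.shape)
    sensogram = Sensogram(t, angle, tir, marks)
    truth = {"plateaus_deg": plateau_angles_deg, "conc_steps": conc_steps,
             "drift_deg_s": drift_deg_s, "noise_deg": noise_deg, "seed": seed}
    return sensogram, truth


def gen_acf(populations, beta: float = 0.9, noise: float = 0.0, seed: int = 0,
            lags_s=None, temperature_K: float = C.ROOM_TEMPERATURE_K,
            viscosity_Pa_s: float = C.WATER_VISCOSITY_PA_S) -> tuple[ACFTrace, dict]:
    """ACF of a (diameter_nm, intensity_weight) population list.

    Additive Gaussian noise on g2-1, log-spaced lags 1 µs - 1 s.
    """
    if lags_s is None:
        lags_s = np.geomspace(1e-6, 1.0, 200)
    diam, w = zip(*populations)
    dist = SizeDistribution(np.asarray(diam, float), np.asarray(w, float))
    g1 = field_acf_model(dist, lags_s, None, temperature_K, viscosity_Pa_s)
    g2m1 = siegert(g1, beta)
    if noise > 0:
        rng = np.random.default_rng(seed)
        g2m1 = g2m1 + noise * rng.standard_normal(g2m1.shape)
    trace = ACFTrace(np.asarray(lags_s, float), g2m1, beta,
                     temperature_K=temperature_K, viscosity_Pa_s=viscosity_Pa_s)
    truth = {"populations": [list(p) for p in populations], "beta": beta,
             "noise": noise, "seed": seed}
    return trace, truth


def gen_aggregation_profile(conc_grid_uM, half_sat_uM: float = 12.0,
                            peak_size_nm: float = 1200.0,
                            coated_size_nm: float = 44.0,
                            pristine_size_nm: float = 30.0,
                            width_dex: float = 0.35,
                            seed: int = 0):
    """Empirical bell-shaped bridging-aggregation size profile.

    Mean size rises from the pristine bead to micron-scale clusters
    peaking at the half-saturation concentration, then relaxes to the
    protein-coated single-bead size; breadth grows with the bell.  This
    is a phenomenological profile, not a flocculation model.

    Returns (list of SizeDistribution, list of median sizes nm).
    """
    grid = default_diameter_grid()
    dists, medians = [], []
    for c in np.asarray(conc_grid_uM, dtype=float):
        theta = c / (half_sat_uM + c)  # Langmuir ramp pristine -> coated
        base = pristine_size_nm + (coated_size_nm - pristine_size_nm) * theta
        bell = peak_size_nm * np.exp(
            -np.log10(c / half_sat_uM) ** 2 / (2 * width_dex ** 2)) if c > 0 else 0.0
        median = base + bell
        gsd = 1.25 + 0.75 * (bell / peak_size_nm)
        w = np.exp(-np.log(grid / median) ** 2 / (2 * np.log(gsd) ** 2))
        dists.append(SizeDistribution(grid, w))
        medians.append(float(median))
    return dists, medians


# ---------------------------------------------------------------------------
# full-scenario fixture
# ---------------------------------------------------------------------------

def _invert_planar_equivalent(va_nm: float, R_nm: float) -> float:
    """Delta_r_h producing a given planar-equivalent V/A on a sphere."""
    if va_nm == 0:
        return 0.0
    f = lambda x: x * (1 + x / R_nm + x ** 2 / (3 * R_nm ** 2)) - va_nm
    return brentq(f, 0.0, va_nm)


def gen_scenario_fixture(seed: int = 0, config: ScenarioConfig | None = None) -> dict:
    """One call producing every input of an end-to-end pipeline run.

    Returns a bundle of in-memory objects plus a ``truth`` record;
    :func:`write_fixture` serialises the bundle to the CSV dialects the
    analysis modules read.
    """
    cfg = config or ScenarioConfig(seed=seed)
    rng = np.random.default_rng(seed)
    hydration = HydrationModel()
    v_eff, _ = hydrated_molar_volume(hydration)

    # --- SPR branch: BSA deposition -------------------------------------
    bsa_conc_uM = np.array([1.2, 3.0, 7.5, 12.0, 30.0, 60.0, 120.0])
    theta = sips_theta(bsa_conc_uM, cfg.sips_K, cfg.sips_n)
    gamma_bsa = cfg.gamma_sat_ng_cm2 * theta
    stack = default_stack(670.0)
    d_bsa = gamma_bsa * cfg.dndc_protein_cm3_g / 100.0 / (C.N_PROTEIN - C.N_BUFFER)

    bsa_scans = {}
    for conc, d in zip(bsa_conc_uM, d_bsa):
        scan, _ = gen_angle_scan(stack, d, C.N_PROTEIN, cfg.scan_noise_rel,
                                 int(rng.integers(2 ** 31)))
        bsa_scans[float(conc)] = scan

    delta_max_deg = 0.229  # plateau scale: 0.15 deg at the 30 µM step
    plateaus = list(delta_max_deg * theta)
    bsa_g_cm3 = bsa_conc_uM * 1e-6 * C.MOLAR_MASS_BSA * 1e-3  # mol/L -> g/cm^3
    sensogram, sensogram_truth = gen_titration_sensogram(
        list(bsa_conc_uM), plateaus, noise_deg=cfg.sensogram_noise_deg,
        dndc_cm3_g=cfg.dndc_protein_cm3_g, conc_g_cm3=list(bsa_g_cm3),
        seed=int(rng.integers(2 ** 31)))

    # dn/dC calibration input (TIR shift of a 0.01 g/cm^3 bulk solution)
    dndc_inputs = pd.DataFrame({
        "analyte": ["protein", "surfactant"],
        "wavelength_nm": [670.0, 670.0],
        "delta_tir_deg": [cfg.dndc_protein_cm3_g * 86.3 * 0.01,
                          cfg.dndc_surfactant_cm3_g * 86.3 * 0.01],
        "conc_g_cm3": [0.01, 0.01],
    })

    # --- SPR branch: surfactant on the protein-coated sensor ------------
    surf_wt_spr = np.array([0.25, 0.5, 1.0, 1.5, 2.0])
    surf_M_spr = np.array([wt_percent_to_mol_per_L(w, C.MOLAR_MASS_C10PEG)
                           for w in surf_wt_spr])
    va_spr = bet_coverage(surf_M_spr, cfg.bet_q1_nm, cfg.bet_K_L_M, cfg.bet_K_ml_M)
    gamma_surf = va_spr * hydration.molar_mass_g_mol * 100.0 / v_eff  # dry ng/cm^2
    d_surf = gamma_surf * cfg.dndc_surfactant_cm3_g / 100.0 / (C.N_SURFACTANT - C.N_BUFFER)
    surf_scans = {}
    for conc, d in zip(surf_M_spr, d_surf):
        scan, _ = gen_angle_scan(stack, d, C.N_SURFACTANT, cfg.scan_noise_rel,
                                 int(rng.integers(2 ** 31)))
        surf_scans[float(conc)] = scan

    # --- DLS branch ------------------------------------------------------
    surf_wt_dls = np.array([0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
    surf_M_dls = np.array([wt_percent_to_mol_per_L(w, C.MOLAR_MASS_C10PEG)
                           for w in surf_wt_dls])
    va_dls = bet_coverage(surf_M_dls, cfg.bet_q1_nm, cfg.bet_K_L_M, cfg.bet_K_ml_M)
    r_h0 = cfg.coated_diameter_nm / 2.0
    delta_rh = np.array([_invert_planar_equivalent(v, cfg.curvature_radius_nm)
                         for v in va_dls])
    diameters = 2.0 * (r_h0 + delta_rh)

    acf_pristine, _ = gen_acf([(cfg.pristine_diameter_nm, 1.0)],
                              noise=cfg.acf_noise, seed=int(rng.integers(2 ** 31)))
    acf_coated, _ = gen_acf([(cfg.coated_diameter_nm, 1.0)],
                            noise=cfg.acf_noise, seed=int(rng.integers(2 ** 31)))
    acf_surf = {}
    for conc, dia in zip(surf_M_dls, diameters):
        trace, _ = gen_acf([(dia, 1.0)], noise=cfg.acf_noise,
                           seed=int(rng.integers(2 ** 31)))
        acf_surf[float(conc)] = trace

    mobility = pd.DataFrame({
        "sample": ["pristine", "bsa_coated"],
        "mobility": [cfg.mobility_pristine, cfg.mobility_coated],
        "mobility_sd": [cfg.mobility_pristine_sd, cfg.mobility_coated_sd],
        "unit": ["um_cm/V_s", "um_cm/V_s"],
        "temperature_K": [C.ROOM_TEMPERATURE_K] * 2,
    })

    agg_conc_uM = np.array([1.2, 3.0, 7.5, 12.0, 30.0, 60.0, 120.0])
    agg_dists, agg_medians = gen_aggregation_profile(
        agg_conc_uM, half_sat_uM=cfg.half_sat_uM,
        coated_size_nm=cfg.coated_diameter_nm,
        pristine_size_nm=cfg.pristine_diameter_nm, seed=seed)

    truth = {
        "config": dataclasses.asdict(cfg),
        "sips": {"K_per_uM_n": cfg.sips_K, "n_het": cfg.sips_n,
                 "gamma_sat_ng_cm2": cfg.gamma_sat_ng_cm2},
        "bet": {"q1_nm": cfg.bet_q1_nm, "K_L_M": cfg.bet_K_L_M,
                "K_ml_M": cfg.bet_K_ml_M},
        "bsa_gamma_ng_cm2": dict(zip(map(float, bsa_conc_uM), map(float, gamma_bsa))),
        "bsa_d_nm": dict(zip(map(float, bsa_conc_uM), map(float, d_bsa))),
        "surf_spr_gamma_ng_cm2": dict(zip(map(float, surf_M_spr), map(float, gamma_surf))),
        "surf_spr_d_nm": dict(zip(map(float, surf_M_spr), map(float, d_surf))),
        "dls_va_nm": dict(zip(map(float, surf_M_dls), map(float, va_dls))),
        "dls_diameter_nm": dict(zip(map(float, surf_M_dls), map(float, diameters))),
        "r_h0_nm": r_h0,
        "sensogram": sensogram_truth,
        "aggregation_median_nm": dict(zip(map(float, agg_conc_uM), agg_medians)),
    }
    return {
        "config": cfg,
        "truth": truth,
        "stack": stack,
        "hydration": hydration,
        "bsa": {"conc_uM": bsa_conc_uM, "scans": bsa_scans,
                "sensogram": sensogram},
        "surfactant_spr": {"conc_M": surf_M_spr, "scans": surf_scans},
        "dndc_inputs": dndc_inputs,
        "dls": {"conc_M": surf_M_dls, "traces": acf_surf,
                "pristine": acf_pristine, "coated": acf_coated,
                "mobility": mobility},
        "aggregation": {"conc_uM": agg_conc_uM, "distributions": agg_dists,
                        "medians_nm": agg_medians},
    }


def write_fixture(bundle: dict, outdir) -> Path:
    """Serialise a fixture bundle to CSV files + a truth JSON sidecar."""
    from . import io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "scans").mkdir(exist_ok=True)
    (outdir / "acf").mkdir(exist_ok=True)

    sio.write_sensogram(bundle["bsa"]["sensogram"], outdir / "bsa_sensogram.csv",
                        outdir / "bsa_marks.csv")

    rows = []
    for conc, scan in bundle["surfactant_spr"]["scans"].items():
        fname = f"scans/surf_{conc:.6g}.csv"
        sio.write_angle_scan(scan, outdir / fname)
        rows.append({"conc": conc, "conc_unit": "mol/L", "file": fname,
                     "adlayer_n": C.N_SURFACTANT, "analyte": "surfactant"})
    for conc, scan in bundle["bsa"]["scans"].items():
        fname = f"scans/bsa_{conc:.6g}.csv"
        sio.write_angle_scan(scan, outdir / fname)
        rows.append({"conc": conc, "conc_unit": "uM", "file": fname,
                     "adlayer_n": C.N_PROTEIN, "analyte": "protein"})
    pd.DataFrame(rows).to_csv(outdir / "scan_index.csv", index=False)

    bundle["dndc_inputs"].to_csv(outdir / "dndc.csv", index=False)

    rows = []
    for conc, trace in bundle["dls"]["traces"].items():
        fname = f"acf/surf_{conc:.6g}.csv"
        sio.write_acf(trace, outdir / fname)
        rows.append({"conc": conc, "conc_unit": "mol/L", "file": fname,
                     "sample": "surfactant"})
    sio.write_acf(bundle["dls"]["pristine"], outdir / "acf/pristine.csv")
    sio.write_acf(bundle["dls"]["coated"], outdir / "acf/coated.csv")
    rows.append({"conc": 0.0, "conc_unit": "mol/L", "file": "acf/pristine.csv",
                 "sample": "pristine"})
    rows.append({"conc": 0.0, "conc_unit": "mol/L", "file": "acf/coated.csv",
                 "sample": "coated"})
    pd.DataFrame(rows).to_csv(outdir / "acf_index.csv", index=False)

    bundle["dls"]["mobility"].to_csv(outdir / "mobility.csv", index=False)

    with open(outdir / "truth.json", "w") as fh:
        json.dump(bundle["truth"], fh, indent=1, sort_keys=True)
    return outdir
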