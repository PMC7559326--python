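"""End-to-end orchestration of the two measurement branches.

The flat-surface (SPR) branch turns angle scans into dry surface
coverage, fits a Sips isotherm and converts coverage to hydrated-film
thickness.  The colloidal (DLS) branch turns autocorrelation traces
into hydrodynamic sizes, applies the sphere-curvature correction and
fits a BET isotherm; electrophoretic mobilities become zeta potentials.
``compare_geometries`` merges the two thickness series into one
planar-equivalent isotherm and reports their discrepancy plus a joint
BET fit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from . import io as sio
from .dls import CumulantSizer
from .electrokinetics import MobilityRecord, smoluchowski_zeta
from .exceptions import ValidationError
from .geometry import (HydrationModel, merge_geometry_series,
                       planar_equivalent_thickness, spr_film_thickness)
from .isotherms import IsothermSeries, fit_isotherm
from .spr import (InstrumentConstants, default_stack, defeijter_coverage,
                  dndc_from_tir_shift, extract_plateaus, fit_layer_thickness)

__all__ = ["RunConfig", "run_spr_branch", "run_dls_branch",
           "compare_geometries", "run_all"]


@dataclass
class RunConfig:
    """Paths and constants for one pipeline run."""

    indir: Path
    outdir: Path
    seed: int = 0
    wavelength_nm: float = 670.0
    curvature_radius_nm: float = 20.0
    thickness_bounds_nm: tuple = (0.0, 50.0)
    hydration: HydrationModel = field(default_factory=HydrationModel)
    instrument: InstrumentConstants = field(default_factory=InstrumentConstants)

    def __post_init__(self):
        self.indir = Path(self.indir)
        self.outdir = Path(self.outdir)
        if not self.indir.exists():
            raise ValidationError(f"input directory {self.indir} does not exist")
        self.outdir.mkdir(parents=True, exist_ok=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        hyd = HydrationModel(**data.pop("hydration", {}))
        inst = data.pop("instrument", {})
        instrument = InstrumentConstants(
            G_deg_per_RIU={float(k): v for k, v in inst.get(
                "G_deg_per_RIU", C.G_FACTOR_DEG_PER_RIU).items()},
            n_buffer=inst.get("n_buffer", C.N_BUFFER))
        if "thickness_bounds_nm" in data:
            data["thickness_bounds_nm"] = tuple(data["thickness_bounds_nm"])
        return cls(hydration=hyd, instrument=instrument, **data)


def _load_dndc(config: RunConfig) -> dict[str, float]:
    path = config.indir / "dndc.csv"
    if not path.exists():
        raise ValidationError(
            "missing dndc.csv: the SPR branch cannot convert optical "
            "thickness to coverage without a refractive-index increment")
    df = pd.read_csv(path)
    out = {}
    for row in df.itertuples(index=False):
        out[row.analyte] = dndc_from_tir_shift(
            row.delta_tir_deg, config.instrument, row.wavelength_nm,
            row.conc_g_cm3)
    return out


def run_spr_branch(config: RunConfig) -> dict:
    """Flat-surface chain: scans -> thickness -> coverage -> Sips fit ->
    hydrated thickness series."""
    dndc = _load_dndc(config)
    index = pd.read_csv(config.indir / "scan_index.csv")
    if index.empty:
        raise ValidationError("scan_index.csv lists no scans")
    stack = default_stack(config.wavelength_nm)

    rows = []
    for r in index.itertuples(index=False):
        scan = sio.read_angle_scan(config.indir / r.file)
        d_fit, rms = fit_layer_thickness(scan, stack, r.adlayer_n,
                                         bounds=config.thickness_bounds_nm)
        cov = defeijter_coverage(d_fit, r.adlayer_n, config.instrument,
                                 dndc[r.analyte])
        rows.append({"analyte": r.analyte, "conc": r.conc,
                     "conc_unit": r.conc_unit, "d_fit_nm": d_fit,
                     "rms_residual": rms, "gamma_ng_cm2": cov.gamma_ng_cm2,
                     "optical_thickness_nm": cov.optical_thickness_nm})
    coverage = pd.DataFrame(rows).sort_values(["analyte", "conc"]).reset_index(drop=True)

    fits = {}
    for analyte, grp in coverage.groupby("analyte"):
        series = IsothermSeries(grp["conc"].to_numpy(),
                                grp["gamma_ng_cm2"].to_numpy(),
                                conc_unit=grp["conc_unit"].iloc[0],
                                response_kind="mass_coverage")
        fits[analyte] = fit_isotherm(series, "sips", random_state=config.seed)

    surf = coverage[coverage["analyte"] == "surfactant"]
    thickness = pd.DataFrame({
        "conc": surf["conc"].to_numpy(),
        "conc_unit": surf["conc_unit"].to_numpy(),
        "thickness_nm": [spr_film_thickness(g, config.hydration).value_nm
                         for g in surf["gamma_ng_cm2"]],
        "source": "spr_hydrated"})

    plateaus = None
    senso_path = config.indir / "bsa_sensogram.csv"
    if senso_path.exists():
        senso = sio.read_sensogram(senso_path, config.indir / "bsa_marks.csv")
        plateaus = pd.DataFrame(
            [dataclasses.asdict(p) for p in extract_plateaus(senso)])

    coverage.to_csv(config.outdir / "spr_coverage.csv", index=False)
    sio.write_thickness_series(thickness, config.outdir / "spr_thickness.csv")
    if plateaus is not None:
        plateaus.to_csv(config.outdir / "spr_plateaus.csv", index=False)
    return {"coverage": coverage, "fits": fits, "thickness": thickness,
            "plateaus": plateaus, "dndc": dndc}


def run_dls_branch(config: RunConfig) -> dict:
    """Colloidal chain: ACFs -> sizes -> curvature-corrected thickness ->
    BET fit; mobilities -> zeta table."""
    index_path = config.indir / "acf_index.csv"
    if not index_path.exists():
        raise ValidationError("missing acf_index.csv for the DLS branch")
    index = pd.read_csv(index_path)

    sizes = []
    for r in index.itertuples(index=False):
        trace = sio.read_acf(config.indir / r.file)
        sizer = CumulantSizer().fit(trace)
        sizes.append({"sample": r.sample, "conc": r.conc,
                      "conc_unit": r.conc_unit,
                      "diameter_nm": sizer.diameter_nm_, "pdi": sizer.pdi_})
    sizes = pd.DataFrame(sizes)

    coated = sizes[sizes["sample"] == "coated"]
    if coated.empty:
        raise ValidationError(
            "no 'coated' baseline trace: cannot form hydrodynamic thickness")
    r_h0 = float(coated["diameter_nm"].iloc[0]) / 2.0

    surf = sizes[sizes["sample"] == "surfactant"].sort_values("conc")
    delta_rh = surf["diameter_nm"].to_numpy() / 2.0 - r_h0
    if np.any(delta_rh < 0):
        raise ValidationError("hydrodynamic radius below the coated baseline")
    corrected = [planar_equivalent_thickness(d, config.curvature_radius_nm).value_nm
                 for d in delta_rh]
    thickness = pd.DataFrame({
        "conc": surf["conc"].to_numpy(),
        "conc_unit": surf["conc_unit"].to_numpy(),
        "thickness_nm": corrected, "source": "dls_curvature_corrected"})
    raw = thickness.assign(thickness_nm=delta_rh, source="dls_raw")

    series = IsothermSeries(thickness["conc"].to_numpy(),
                            thickness["thickness_nm"].to_numpy(),
                            conc_unit=thickness["conc_unit"].iloc[0],
                            response_kind="volume_coverage")
    bet = fit_isotherm(series, "bet", random_state=config.seed)

    zeta_rows = []
    mob_path = config.indir / "mobility.csv"
    if mob_path.exists():
        for r in pd.read_csv(mob_path).itertuples(index=False):
            rec = MobilityRecord(r.mobility, r.unit,
                                 temperature_K=getattr(r, "temperature_K", C.ROOM_TEMPERATURE_K),
                                 mobility_sd=getattr(r, "mobility_sd", 0.0))
            z, sd = smoluchowski_zeta(rec)
            zeta_rows.append({"sample": r.sample, "mobility": r.mobility,
                              "unit": r.unit, "zeta_mV": z, "zeta_sd_mV": sd})
    zeta = pd.DataFrame(zeta_rows)

    sizes.to_csv(config.outdir / "dls_sizes.csv", index=False)
    sio.write_thickness_series(thickness, config.outdir / "dls_thickness.csv")
    sio.write_thickness_series(raw, config.outdir / "dls_thickness_raw.csv")
    if len(zeta):
        zeta.to_csv(config.outdir / "zeta.csv", index=False)
    return {"sizes": sizes, "r_h0_nm": r_h0, "thickness": thickness,
            "thickness_raw": raw, "bet": bet, "zeta": zeta}


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def compare_geometries(spr_results: dict, dls_results: dict,
                       config: RunConfig) -> dict:
    """Merge the two planar-equivalent thickness series and report."""
    spr_t = spr_results.get("thickness") if spr_results else None
    dls_t = dls_results.get("thickness") if dls_results else None
    merged, discrepancy = merge_geometry_series(spr_t, dls_t)

    joint_bet = None
    agg = merged.groupby("conc", as_index=False)["thickness_nm"].mean()
    if len(agg) >= 5:
        series = IsothermSeries(agg["conc"].to_numpy(),
                                agg["thickness_nm"].to_numpy(),
                                conc_unit=merged["conc_unit"].iloc[0],
                                response_kind="volume_coverage")
        joint_bet = fit_isotherm(series, "bet", random_state=config.seed)

    report = {
        "seed": config.seed,
        "constants": C.constants_table(),
        "hydration": dataclasses.asdict(config.hydration),
        "curvature_radius_nm": config.curvature_radius_nm,
        "merged_series": merged,
        "mean_abs_discrepancy_nm": discrepancy,
        "spr_fits": {k: _jsonify(v) for k, v in
                     (spr_results.get("fits") or {}).items()} if spr_results else {},
        "dls_bet_fit": _jsonify(dls_results.get("bet")) if dls_results else None,
        "joint_bet_fit": _jsonify(joint_bet),
        "zeta_table": dls_results.get("zeta") if dls_results else None,
    }
    sio.write_thickness_series(merged, config.outdir / "merged_thickness.csv")
    with open(config.outdir / "comparison_report.json", "w") as fh:
        json.dump(_jsonify(report), fh, indent=1, sort_keys=True)
    return report


def run_all(config: RunConfig) -> dict:
    spr = run_spr_branch(config)
    dls = run_dls_branch(config)
    report = compare_geometries(spr, dls, config)
    return {"spr": spr, "dls": dls, "report": report}
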