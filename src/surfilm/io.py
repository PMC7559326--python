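"""Delimited-text readers and writers for the pipeline's data types.

All on-disk formats are plain CSV; stack definitions and run
configuration use YAML.  Units are carried as explicit columns, never
inferred.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dls import ACFTrace, SizeDistribution
from .exceptions import ValidationError
from .isotherms import IsothermSeries
from .spr import AngleScan, LayerStack, OpticalLayer, Sensogram

_FLOAT_FMT = "%.10g"


# --- angle scans -----------------------------------------------------------

def write_angle_scan(scan: AngleScan, path) -> None:
    pd.DataFrame({"angle_deg": scan.angles_deg,
                  "reflectivity": scan.reflectivity}
                 ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_angle_scan(path) -> AngleScan:
    df = pd.read_csv(path)
    return AngleScan(df["angle_deg"].to_numpy(), df["reflectivity"].to_numpy())


# --- sensograms ------------------------------------------------------------

def write_sensogram(s: Sensogram, path, marks_path) -> None:
    pd.DataFrame({"time_s": s.time_s, "min_angle_deg": s.min_angle_deg,
                  "tir_angle_deg": s.tir_angle_deg}
                 ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(s.injection_marks,
                 columns=["start_s", "end_s", "label", "conc"]
                 ).to_csv(marks_path, index=False, float_format=_FLOAT_FMT)


def read_sensogram(path, marks_path) -> Sensogram:
    df = pd.read_csv(path)
    marks = [tuple(r) for r in pd.read_csv(marks_path)
             [["start_s", "end_s", "label", "conc"]].itertuples(index=False)]
    return Sensogram(df["time_s"].to_numpy(), df["min_angle_deg"].to_numpy(),
                     df["tir_angle_deg"].to_numpy(), marks)


# --- DLS -------------------------------------------------------------------

def write_acf(trace: ACFTrace, path) -> None:
    df = pd.DataFrame({"lag_s": trace.lags_s, "g2m1": trace.g2m1})
    df.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# beta={trace.beta} temperature_K={trace.temperature_K} "
                 f"viscosity_Pa_s={trace.viscosity_Pa_s}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_acf(path) -> ACFTrace:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                k, _, v = token.partition("=")
                meta[k] = float(v)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return ACFTrace(df["lag_s"].to_numpy(), df["g2m1"].to_numpy(),
                    beta=meta.get("beta", 0.9),
                    temperature_K=meta.get("temperature_K", 298.15),
                    viscosity_Pa_s=meta.get("viscosity_Pa_s", 8.9e-4))


def write_distribution(dist: SizeDistribution, path) -> None:
    pd.DataFrame({"diameter_nm": dist.diameters_nm,
                  "intensity_fraction": dist.weights}
                 ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_distribution(path) -> SizeDistribution:
    df = pd.read_csv(path)
    return SizeDistribution(df["diameter_nm"].to_numpy(),
                            df["intensity_fraction"].to_numpy())


# --- isotherms and thickness series ---------------------------------------

def write_isotherm(series: IsothermSeries, path) -> None:
    df = pd.DataFrame({"conc": series.conc, "conc_unit": series.conc_unit,
                       "response": series.response,
                       "response_kind": series.response_kind})
    if series.sigma is not None:
        df["sigma"] = series.sigma
    if series.source is not None:
        df["source"] = series.source
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_isotherm(path) -> IsothermSeries:
    df = pd.read_csv(path)
    units = df["conc_unit"].unique()
    kinds = df["response_kind"].unique()
    if len(units) != 1 or len(kinds) != 1:
        raise ValidationError("isotherm file mixes units or response kinds")
    return IsothermSeries(
        df["conc"].to_numpy(), df["response"].to_numpy(),
        conc_unit=units[0], response_kind=kinds[0],
        sigma=df["sigma"].to_numpy() if "sigma" in df else None,
        source=df["source"].iloc[0] if "source" in df else None)


def write_thickness_series(df: pd.DataFrame, path) -> None:
    required = {"conc", "conc_unit", "thickness_nm", "source"}
    if not required.issubset(df.columns):
        raise ValidationError(f"thickness series needs columns {sorted(required)}")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_thickness_series(path) -> pd.DataFrame:
    return pd.read_csv(path)


# --- stacks ----------------------------------------------------------------

def write_stack_yaml(stack: LayerStack, path) -> None:
    data = {"wavelength_nm": stack.wavelength_nm, "layers": [
        {"name": lay.name, "n_real": float(np.real(lay.n_complex)),
         "n_imag": float(np.imag(lay.n_complex)),
         "thickness_nm": lay.thickness_nm}
        for lay in stack.layers]}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_stack_yaml(path) -> LayerStack:
    data = yaml.safe_load(Path(path).read_text())
    layers = tuple(
        OpticalLayer(d["name"], complex(d["n_real"], d.get("n_imag", 0.0)),
                     d.get("thickness_nm"))
        for d in data["layers"])
    return LayerStack(layers, data["wavelength_nm"])
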