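"""File formats: CSV tables, photon records, parameter/config serialization.

All on-disk units are SI (seconds, molar, s^-1); timestamps are integer
nanoseconds.  Readers raise informative errors naming the offending file and
field; header-only tables load as zero-row frames.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Union

import numpy as np
import pandas as pd
import yaml

from .assays import ProductTimeCourse
from .fitting import ActivityDataset
from .fret.bursts import PhotonStream
from .params import Conditions, ConformationalRates, LIGATION_STATES, ModelParameters

PathLike = Union[str, Path]


def _read_csv(path: PathLike, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: file is empty")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}; found {list(df.columns)}")
    for col in required:
        if len(df) and not np.issubdtype(df[col].dtype, np.number):
            bad = df[~pd.to_numeric(df[col], errors="coerce").notna()].index
            raise ValueError(f"{path}: non-numeric values in column '{col}' at rows {list(bad[:5])}")
    return df


# --- velocity / activity tables -------------------------------------------

def write_velocity_csv(table: pd.DataFrame, path: PathLike) -> None:
    table[["conc_M", "velocity_per_s"]].to_csv(path, index=False)


def read_velocity_csv(path: PathLike) -> pd.DataFrame:
    return _read_csv(path, ("conc_M", "velocity_per_s"))


def write_activity_csv(dataset: ActivityDataset, path: PathLike) -> None:
    pd.DataFrame({"conc_M": dataset.conc, "v0_per_s": dataset.v0, "sem": dataset.sem}).to_csv(
        path, index=False)


def read_activity_csv(path: PathLike, axis: str, fixed_conc: float, urea: float) -> ActivityDataset:
    df = _read_csv(path, ("conc_M", "v0_per_s", "sem"))
    return ActivityDataset(axis=axis, fixed_conc=fixed_conc, urea=urea,
                           conc=df["conc_M"].to_numpy(), v0=df["v0_per_s"].to_numpy(),
                           sem=df["sem"].to_numpy())


# --- titrations and time courses ------------------------------------------

def write_titration_csv(table: pd.DataFrame, path: PathLike) -> None:
    table[["conc_M", "fraction_bound"]].to_csv(path, index=False)


def read_titration_csv(path: PathLike) -> pd.DataFrame:
    return _read_csv(path, ("conc_M", "fraction_bound"))


def write_timecourse_csv(tc: ProductTimeCourse, path: PathLike) -> None:
    pd.DataFrame({"time_s": tc.times, "product_M": tc.product}).to_csv(path, index=False)


def read_timecourse_csv(path: PathLike, direction: str = "reverse") -> ProductTimeCourse:
    df = _read_csv(path, ("time_s", "product_M"))
    return ProductTimeCourse(times=df["time_s"].to_numpy(), product=df["product_M"].to_numpy(),
                             direction=direction)


# --- photon streams ---------------------------------------------------------

def write_photon_csv(stream: PhotonStream, path: PathLike) -> None:
    pd.DataFrame({
        "timestamp_ns": stream.timestamps_ns,
        "channel": stream.channel,
        "excitation": stream.excitation,
    }).to_csv(path, index=False)


def read_photon_csv(path: PathLike) -> PhotonStream:
    df = _read_csv(path, ("timestamp_ns", "channel", "excitation"))
    return PhotonStream(
        timestamps_ns=df["timestamp_ns"].to_numpy(np.int64),
        channel=df["channel"].to_numpy(np.uint8),
        excitation=df["excitation"].to_numpy(np.uint8),
    )


def write_photon_hdf5(stream: PhotonStream, path: PathLike) -> None:
    """Write a minimal Photon-HDF5-style layout (photon_data group)."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=stream.timestamps_ns)
        g.create_dataset("detectors", data=stream.channel)
        g.create_dataset("excitation", data=stream.excitation)
        g.create_dataset("timestamps_specs/timestamps_unit", data=1e-9)


def read_photon_hdf5(path: PathLike) -> PhotonStream:
    """Read a Photon-HDF5-style file (photon_data/timestamps + detectors).

    Timestamps are converted to nanoseconds using
    ``timestamps_specs/timestamps_unit`` when present (default 1 ns).  An
    ``excitation`` dataset is honored; otherwise all photons are treated as
    donor-excitation.
    """
    import h5py

    with h5py.File(path, "r") as f:
        if "photon_data" not in f:
            raise ValueError(f"{path}: no photon_data group")
        g = f["photon_data"]
        for name in ("timestamps", "detectors"):
            if name not in g:
                raise ValueError(f"{path}: photon_data/{name} missing")
        unit = 1e-9
        if "timestamps_specs/timestamps_unit" in g:
            unit = float(g["timestamps_specs/timestamps_unit"][()])
        ts = np.round(np.asarray(g["timestamps"]) * (unit / 1e-9)).astype(np.int64)
        detectors = np.asarray(g["detectors"]).astype(np.uint8)
        if "excitation" in g:
            exc = np.asarray(g["excitation"]).astype(np.uint8)
        else:
            exc = np.zeros_like(detectors)
    return PhotonStream(timestamps_ns=ts, channel=detectors, excitation=exc)


# --- parameters and configuration -------------------------------------------

def parameters_to_dict(params: ModelParameters) -> Dict:
    return {
        "k_cat": params.k_cat,
        "k_r_T": params.k_r_T,
        "k_r_M": params.k_r_M,
        "Kd_ATP": params.Kd_ATP,
        "Kd_AMP": params.Kd_AMP,
        "k_on": params.k_on,
        "conformational_rates": {
            "k_open": dict(params.conformational_rates.k_open),
            "k_close": dict(params.conformational_rates.k_close),
        },
    }


def parameters_from_dict(data: Mapping) -> ModelParameters:
    required = {"k_cat", "k_r_T", "k_r_M", "Kd_ATP", "Kd_AMP", "conformational_rates"}
    missing = required - set(data)
    if missing:
        raise ValueError(f"parameter dict missing fields {sorted(missing)}")
    cr = data["conformational_rates"]
    rates = ConformationalRates(
        k_open={lig: float(cr["k_open"][lig]) for lig in LIGATION_STATES},
        k_close={lig: float(cr["k_close"][lig]) for lig in LIGATION_STATES},
    )
    return ModelParameters(
        k_cat=float(data["k_cat"]), k_r_T=float(data["k_r_T"]), k_r_M=float(data["k_r_M"]),
        Kd_ATP=float(data["Kd_ATP"]), Kd_AMP=float(data["Kd_AMP"]),
        k_on=float(data.get("k_on", 1e8)), conformational_rates=rates,
    )


def write_parameters_json(params: ModelParameters, path: PathLike) -> None:
    Path(path).write_text(json.dumps(parameters_to_dict(params), indent=2))


def read_parameters_json(path: PathLike) -> ModelParameters:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: file is empty")
    return parameters_from_dict(json.loads(path.read_text()))


def read_config(path: PathLike) -> Dict:
    """Read a YAML/JSON run configuration."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: file is empty")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
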