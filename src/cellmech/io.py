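"""Delimited-text readers/writers and the run manifest.

All inputs are comma-delimited tables with optional ``# key=value``
header lines carrying per-file metadata (pressures, pipette radius,
instrument constants). Columns carry explicit unit suffixes
(``length_um``, ``load_nn``, ``t_min``); readers convert to SI on load
so the numeric core never sees mixed units.

Schemas
-------
creep            time_s, length_um      headers: delta_p_pa (required), rp_um (default 3.5)
indent_raw       z_um, d_um             headers: spring_constant_n_per_m, tip_radius_um, ...
indent_reduced   depth_um, load_nn      headers: as above
tracks           cell_id, t_min, x_um, y_um
wound            day, area_mm2
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, TableFormatError
from .types import (
    CreepRecord,
    IndentationCurve,
    InstrumentConfig,
    Trajectory,
    WoundSeries,
)

__all__ = ["read_table", "write_results", "read_header_meta", "load_config",
           "write_creep_record", "write_indentation_curve"]

SCHEMAS = {
    "creep": ["time_s", "length_um"],
    "indent_raw": ["z_um", "d_um"],
    "indent_reduced": ["depth_um", "load_nn"],
    "tracks": ["cell_id", "t_min", "x_um", "y_um"],
    "wound": ["day", "area_mm2"],
}

_CONFIG_KEYS = {
    "spring_constant_n_per_m", "tip_radius_um", "max_depth_um", "load_period_s",
    "delta_p_pa", "rp_um", "gradient_axis", "frame_min", "seed", "out",
    "log_level", "plateau_fraction", "method", "depth_fraction", "mode",
}


def read_header_meta(path: Union[str, Path]) -> dict:
    """Parse leading ``# key=value`` comment lines into a dict of floats
    (strings kept when not numeric)."""
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" not in body:
                continue
            key, _, val = body.partition("=")
            key, val = key.strip(), val.strip()
            try:
                meta[key] = float(val)
            except ValueError:
                meta[key] = val
    return meta


def _load_frame(path: Union[str, Path], schema: str) -> pd.DataFrame:
    cols = SCHEMAS[schema]
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except Exception as exc:
        raise TableFormatError(f"{path}: cannot parse as delimited text ({exc})") from exc
    df.columns = [c.strip() for c in df.columns]
    for col in cols:
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r} "
                                   f"(schema {schema!r})")
    numeric_cols = [c for c in cols if c != "cell_id"]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2  # 1-based + header line
            raise TableFormatError(
                f"{path}: non-numeric value in column {col!r} at data row {row}"
            )
        df[col] = coerced
    return df


def _check_monotone(path, t: np.ndarray, column: str) -> None:
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise TableFormatError(
            f"{path}: column {column!r} not strictly increasing at data row {int(bad[0]) + 2}"
        )


def _instrument_from_meta(meta: dict) -> InstrumentConfig:
    kw = {}
    if "spring_constant_n_per_m" in meta:
        kw["spring_constant"] = float(meta["spring_constant_n_per_m"])
    if "tip_radius_um" in meta:
        kw["tip_radius"] = float(meta["tip_radius_um"]) * 1e-6
    if "max_depth_um" in meta:
        kw["max_depth"] = float(meta["max_depth_um"]) * 1e-6
    if "load_period_s" in meta:
        kw["load_period"] = float(meta["load_period_s"])
    return InstrumentConfig(**kw)


def read_table(path: Union[str, Path], schema_name: str):
    """Read and validate one input file; returns SI-unit domain objects.

    Returns a :class:`CreepRecord`, an :class:`IndentationCurve`, a list
    of :class:`Trajectory`, or a :class:`WoundSeries` depending on the
    schema. Errors name the file, row and column.
    """
    if schema_name not in SCHEMAS:
        raise ConfigError(f"unknown schema {schema_name!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = read_header_meta(path)
    df = _load_frame(path, schema_name)

    if schema_name == "creep":
        if "delta_p_pa" not in meta:
            raise TableFormatError(f"{path}: missing '# delta_p_pa=...' header")
        rp_um = float(meta.get("rp_um", 3.5))
        t = df["time_s"].to_numpy(float)
        _check_monotone(path, t, "time_s")
        return CreepRecord(
            delta_p=float(meta["delta_p_pa"]),
            rp=rp_um * 1e-6,
            times=t,
            lengths=df["length_um"].to_numpy(float) * 1e-6,
            meta={"source": str(path), **meta},
        )

    if schema_name in ("indent_raw", "indent_reduced"):
        instrument = _instrument_from_meta(meta)
        if schema_name == "indent_raw":
            x = df["z_um"].to_numpy(float) * 1e-6
            y = df["d_um"].to_numpy(float) * 1e-6
            mode = "raw"
        else:
            x = df["depth_um"].to_numpy(float) * 1e-6
            y = df["load_nn"].to_numpy(float) * 1e-9
            mode = "reduced"
        return IndentationCurve(mode=mode, x=x, y=y, instrument=instrument,
                                meta={"source": str(path), **meta})

    if schema_name == "tracks":
        axis = meta.get("gradient_axis", "x")
        ax = {"x": (1.0, 0.0), "y": (0.0, 1.0), "-x": (-1.0, 0.0), "-y": (0.0, -1.0)}.get(
            axis if isinstance(axis, str) else "x", (1.0, 0.0))
        out: List[Trajectory] = []
        for cid, sub in df.groupby("cell_id", sort=False):
            t = sub["t_min"].to_numpy(float) * 60.0
            _check_monotone(path, t, f"t_min (cell {cid})")
            out.append(Trajectory(
                cell_id=str(cid),
                times=t,
                xs=sub["x_um"].to_numpy(float),
                ys=sub["y_um"].to_numpy(float),
                gradient_axis=ax,
            ))
        return out

    # wound
    days = df["day"].to_numpy(float)
    _check_monotone(path, days, "day")
    return WoundSeries(days=days, areas=df["area_mm2"].to_numpy(float))


def _sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    results: pd.DataFrame,
    path: Union[str, Path],
    config: Optional[dict] = None,
    seed: Optional[int] = None,
    inputs: Sequence[Union[str, Path]] = (),
    rejects: Optional[pd.DataFrame] = None,
) -> dict:
    """Write a results table plus a JSON run manifest.

    The manifest echoes the configuration, seed, package version and
    SHA-256 checksums of the inputs — enough to reproduce the run
    byte-for-byte (no timestamps, deliberately). Failed fits go to a
    sibling ``*.rejects.csv`` with reasons. Returns the manifest dict.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, index=False)
    manifest = {
        "package": "cellmech",
        "version": __version__,
        "seed": seed,
        "config": config or {},
        "inputs": {str(p): _sha256(p) for p in inputs},
        "output": path.name,
        "rows": int(len(results)),
    }
    if rejects is not None and len(rejects):
        rej_path = path.with_suffix(".rejects.csv")
        rejects.to_csv(rej_path, index=False)
        manifest["rejects"] = rej_path.name
        manifest["n_rejected"] = int(len(rejects))
    with open(path.with_suffix(path.suffix + ".manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def write_creep_record(record: CreepRecord, path: Union[str, Path]) -> None:
    """Emit a creep record in the same format :func:`read_table` reads."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# delta_p_pa={record.delta_p!r}\n")
        fh.write(f"# rp_um={record.rp * 1e6!r}\n")
        pd.DataFrame({
            "time_s": record.times,
            "length_um": record.lengths * 1e6,
        }).to_csv(fh, index=False)


def write_indentation_curve(curve: IndentationCurve, path: Union[str, Path]) -> None:
    """Emit an indentation curve in the format :func:`read_table` reads."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ins = curve.instrument
    with open(path, "w") as fh:
        fh.write(f"# spring_constant_n_per_m={ins.spring_constant!r}\n")
        fh.write(f"# tip_radius_um={ins.tip_radius * 1e6!r}\n")
        fh.write(f"# max_depth_um={ins.max_depth * 1e6!r}\n")
        fh.write(f"# load_period_s={ins.load_period!r}\n")
        if curve.mode == "raw":
            df = pd.DataFrame({"z_um": curve.x * 1e6, "d_um": curve.y * 1e6})
        else:
            df = pd.DataFrame({"depth_um": curve.x * 1e6, "load_nn": curve.y * 1e9})
        df.to_csv(fh, index=False)


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML run configuration, rejecting unknown keys up front."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg
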