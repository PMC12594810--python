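"""CSV readers/writers, the packaged reference table and the JSON report.

The canonical on-disk dialect is tidy, comma-separated, UTF-8, header
row mandatory, ``.`` decimal separator.  One file holds many replicates
in long form; readers group rows into the measurement containers of
:mod:`rheojet.datatypes`.

Viscosities are stored internally in mPa·s.  A reader given a table
whose viscosity column is named ``viscosity_pa_s`` converts to mPa·s on
ingest and flags the conversion, so downstream thresholds always see
one unit.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from pathlib import Path
from typing import Any, Iterable, Union

import numpy as np
import pandas as pd

from .datatypes import (
    FlowCurve,
    MediumRecord,
    OscSweep,
    SweepKind,
    ThixoTrace,
    parse_stability_glyph,
)
from .errors import SchemaError, ValidationError

__all__ = [
    "read_flowcurves",
    "write_flowcurves",
    "read_thixotraces",
    "write_thixotraces",
    "read_oscsweeps",
    "write_oscsweeps",
    "load_reference_table",
    "write_report",
    "read_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1.0"

PathLike = Union[str, Path]


def _read_table(path: PathLike, required: Iterable[str], **dialect: Any) -> pd.DataFrame:
    df = pd.read_csv(path, **dialect)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no records")
    return df


def _viscosity_column(df: pd.DataFrame) -> tuple[pd.Series, bool]:
    """Return the viscosity column in mPa·s, converting from Pa·s when
    the column is explicitly flagged as such."""
    if "viscosity" in df.columns:
        return df["viscosity"], False
    if "viscosity_pa_s" in df.columns:
        return df["viscosity_pa_s"] * 1e3, True
    raise SchemaError("missing column(s) viscosity")


def read_flowcurves(path: PathLike, **dialect: Any) -> list[FlowCurve]:
    """Read flow curves from a tidy CSV.

    Expected columns: ``sample_id, replicate_id, shear_rate, viscosity``
    (optionally ``temperature``, ``humidity``; optionally
    ``viscosity_pa_s`` instead of ``viscosity``).  Rows are sorted by
    shear rate within each (sample, replicate) group, so row order in
    the file is immaterial.
    """
    df = _read_table(path, ["sample_id", "replicate_id", "shear_rate"], **dialect)
    eta, converted = _viscosity_column(df)
    df = df.assign(viscosity=eta)
    curves = []
    for (sample, rep), grp in df.groupby(["sample_id", "replicate_id"], sort=True):
        grp = grp.sort_values("shear_rate")
        kwargs = {}
        for opt in ("temperature", "humidity"):
            if opt in grp.columns:
                kwargs[opt] = float(grp[opt].iloc[0])
        curve = FlowCurve(
            sample_id=str(sample),
            replicate_id=int(rep),
            shear_rate=grp["shear_rate"].to_numpy(),
            viscosity=grp["viscosity"].to_numpy(),
            **kwargs,
        )
        object.__setattr__(curve, "_unit_converted", converted)
        curves.append(curve)
    return curves


def write_flowcurves(curves: Iterable[FlowCurve], path: PathLike) -> None:
    rows = []
    for c in curves:
        for g, e in zip(c.shear_rate, c.viscosity):
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "replicate_id": c.replicate_id,
                    "shear_rate": g,
                    "viscosity": e,
                    "temperature": c.temperature,
                    "humidity": c.humidity,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_thixotraces(path: PathLike, **dialect: Any) -> list[ThixoTrace]:
    """Read thixotropy traces (columns ``sample_id, time, shear_rate,
    viscosity, phase`` and optionally ``replicate_id``)."""
    df = _read_table(path, ["sample_id", "time", "shear_rate", "phase"], **dialect)
    eta, _ = _viscosity_column(df)
    df = df.assign(viscosity=eta)
    if "replicate_id" not in df.columns:
        df = df.assign(replicate_id=0)
    traces = []
    for (sample, rep), grp in df.groupby(["sample_id", "replicate_id"], sort=True):
        grp = grp.sort_values("time", kind="stable")
        traces.append(
            ThixoTrace(
                sample_id=str(sample),
                replicate_id=int(rep),
                time=grp["time"].to_numpy(),
                shear_rate=grp["shear_rate"].to_numpy(),
                viscosity=grp["viscosity"].to_numpy(),
                phase=list(grp["phase"]),
            )
        )
    return traces


def write_thixotraces(traces: Iterable[ThixoTrace], path: PathLike) -> None:
    rows = []
    for t in traces:
        for ti, g, e, p in zip(t.time, t.shear_rate, t.viscosity, t.phase):
            rows.append(
                {
                    "sample_id": t.sample_id,
                    "replicate_id": t.replicate_id,
                    "time": ti,
                    "shear_rate": g,
                    "viscosity": e,
                    "phase": p,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_oscsweeps(path: PathLike, **dialect: Any) -> list[OscSweep]:
    """Read oscillatory sweeps (columns ``sample_id, sweep_kind, x,
    g_prime, g_double_prime``)."""
    df = _read_table(
        path, ["sample_id", "sweep_kind", "x", "g_prime", "g_double_prime"], **dialect
    )
    sweeps = []
    for (sample, kind), grp in df.groupby(["sample_id", "sweep_kind"], sort=True):
        grp = grp.sort_values("x")
        sweeps.append(
            OscSweep(
                sample_id=str(sample),
                sweep_kind=SweepKind(str(kind)),
                x=grp["x"].to_numpy(),
                g_prime=grp["g_prime"].to_numpy(),
                g_double_prime=grp["g_double_prime"].to_numpy(),
            )
        )
    return sweeps


def write_oscsweeps(sweeps: Iterable[OscSweep], path: PathLike) -> None:
    rows = []
    for s in sweeps:
        for x, gp, gpp in zip(s.x, s.g_prime, s.g_double_prime):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "sweep_kind": s.sweep_kind.value,
                    "x": x,
                    "g_prime": gp,
                    "g_double_prime": gpp,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_reference_table() -> list[MediumRecord]:
    """Load the packaged reference table of LCP media.

    22 records: the pure LCP reference (70:30 v/v monoolein:water) and
    21 additive-supplemented media, each with mean ± s.d. viscosity at
    the 0.3 s⁻¹ (linear-viscoelastic) and 75.4 s⁻¹ (jet) reference
    shear rates and the observed jetting-stability label.
    """
    resource = importlib.resources.files("rheojet.data") / "lcp_additive_viscosity.csv"
    with importlib.resources.as_file(resource) as p:
        df = pd.read_csv(p)
    records = []
    for _, row in df.iterrows():
        records.append(
            MediumRecord(
                name=row["name"],
                additive=None if pd.isna(row["additive"]) else str(row["additive"]),
                mw=None if pd.isna(row["mw"]) else float(row["mw"]),
                additive_pct_aqueous=(
                    None if pd.isna(row["conc_aqueous"]) else float(row["conc_aqueous"])
                ),
                conc_unit=str(row["conc_unit"]),
                additive_pct_total=(
                    None if pd.isna(row["conc_total"]) else float(row["conc_total"])
                ),
                conc_display=str(row["conc_display"]),
                eta_lve=float(row["eta_lve_mean"]),
                eta_lve_sd=float(row["eta_lve_sd"]),
                eta_jet=float(row["eta_jet_mean"]),
                eta_jet_sd=float(row["eta_jet_sd"]),
                label=parse_stability_glyph(str(row["stability"])),
            )
        )
    return records


def _jsonify(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays, enums and dataclasses
    to plain JSON types."""
    import dataclasses
    import enum as _enum

    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, _enum.Enum):
        return obj.value
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def input_digest(paths: Iterable[PathLike]) -> str:
    """SHA-256 digest over the byte content of the input files, in
    sorted path order; provenance stamp for reports."""
    h = hashlib.sha256()
    for p in sorted(str(p) for p in paths):
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def write_report(results: Any, path: PathLike, *, parameters: Any = None,
                 inputs: Iterable[PathLike] = ()) -> dict:
    """Write a JSON analysis report.

    The document carries a schema version, a digest of the input files,
    the parameters in force and the serialized ``results``; it
    round-trips losslessly through :func:`read_report`.
    """
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "input_digest": input_digest(inputs) if inputs else None,
        "parameters": _jsonify(parameters) if parameters is not None else {},
        "results": _jsonify(results),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc


def read_report(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
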