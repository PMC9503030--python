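"""File formats for dwell sample tables, results and summaries.

The on-disk sample format is a single *long* (tidy) delimited table —
comma- or tab-separated with a header — because dwells have ragged
sampling schedules and mixed units.  Columns::

    dwell_id, animal_id, compartment, solute, time_min, value, unit

``compartment`` is one of ``dialysate``, ``plasma``,
``effluent_diagnostics`` or ``meta``.  For diagnostics and meta rows the
``solute`` column carries the field name (e.g. ``instilled_volume``,
``culture_positive``) and ``time_min`` is empty.  Units are declared per
row and converted at ingest; internal units are fixed (min, mL, mM for
small solutes, g/L for proteins).

Results are written as one machine-readable JSON file per run (every
transport report with its flags, the configuration echo, the package
version and the seed — enough to re-run exactly) plus a delimited summary
table in the parameter x group layout of a transport-characteristics
table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    PROTEIN_SOLUTES,
    SMALL_SOLUTES,
    SOLUTES,
    DwellSamples,
    PlasmaSeries,
    SoluteSeries,
    SPAError,
    SPAResult,
)
from .diagnostics import EffluentDiagnostics, StratifiedSummary

__all__ = [
    "ParseError",
    "RunConfig",
    "read_dwell_tables",
    "write_dwell_tables",
    "write_results",
    "write_summary",
    "read_results",
    "truth_to_dict",
]

COLUMNS = ["dwell_id", "animal_id", "compartment", "solute", "time_min", "value", "unit"]

_MOLAR_UNITS = {"mM": 1.0, "mmol/L": 1.0, "uM": 1e-3, "µM": 1e-3, "umol/L": 1e-3,
                "mol/L": 1e3}
_MASS_CONC_UNITS = {"g/L": 1.0, "g/dL": 10.0, "mg/L": 1e-3}
_VOLUME_UNITS = {"mL": 1.0, "L": 1e3, "dL": 1e2}
_TIME_UNITS = {"min": 1.0, "h": 60.0}
_WEIGHT_UNITS = {"kg": 1.0}
_LEUKO_UNITS = {"10^9/L": 1.0, "x10^9/L": 1.0, "1e9/L": 1.0, "G/L": 1.0}
_BOOL_UNITS = {"bool": 1.0, "": 1.0}

_META_FIELDS = {
    "instilled_volume": _VOLUME_UNITS,
    "drain_volume_end": _VOLUME_UNITS,
    "sample_volume_total": _VOLUME_UNITS,
    "flush_volume": _VOLUME_UNITS,
    "duration": _TIME_UNITS,
    "body_weight": _WEIGHT_UNITS,
    "albumin_overnight_effluent": _MASS_CONC_UNITS,
    "albumin_final_drain": _MASS_CONC_UNITS,
    "albumin_flush": _MASS_CONC_UNITS,
}
_DIAG_FIELDS = {
    "culture_positive": _BOOL_UNITS,
    "cloudy_effluent": _BOOL_UNITS,
    "leukocyte_count": _LEUKO_UNITS,
}


class ParseError(SPAError):
    """Malformed sample table; the message names the offending line."""


def _conc_units(solute: str) -> dict[str, float]:
    return _MASS_CONC_UNITS if solute in PROTEIN_SOLUTES else _MOLAR_UNITS


def _convert(value: float, unit: str, allowed: dict[str, float], where: str) -> float:
    if unit not in allowed:
        raise ParseError(
            f"{where}: unit {unit!r} not in allowed set {sorted(allowed)}"
        )
    return value * allowed[unit]


def read_dwell_tables(path: str | Path) -> list[DwellSamples]:
    """Read a tidy sample table into grouped, unit-normalized dwells.

    Dwells appear in first-occurrence order.  Malformed rows (unknown
    compartments or solutes, bad units, unparseable numbers, duplicated
    keys) raise :class:`ParseError` naming the file line.  Dwells with
    missing optional measurements load; the analysis layer flags whatever
    cannot be computed from them.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory columns {missing}")

    # header is line 1; data row i is line i + 2
    keys: dict[tuple, int] = {}
    dwell_order: list[str] = []
    rows_by_dwell: dict[str, list[tuple[int, pd.Series]]] = {}
    for i, row in df.iterrows():
        line = i + 2
        dwell_id = row["dwell_id"].strip()
        if not dwell_id:
            raise ParseError(f"{path}:{line}: empty dwell_id")
        compartment = row["compartment"].strip()
        solute = row["solute"].strip()
        key = (dwell_id, compartment, solute, row["time_min"].strip())
        if key in keys:
            raise ParseError(
                f"{path}:{line}: duplicate key {key} (first seen at line {keys[key]})"
            )
        keys[key] = line
        if dwell_id not in rows_by_dwell:
            dwell_order.append(dwell_id)
            rows_by_dwell[dwell_id] = []
        rows_by_dwell[dwell_id].append((line, row))

    return [_assemble_dwell(path, d, rows_by_dwell[d]) for d in dwell_order]


def _parse_float(path, line, text: str, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"{path}:{line}: unparseable {what} {text!r}") from None


def _assemble_dwell(path, dwell_id: str, rows) -> DwellSamples:
    meta: dict[str, float] = {}
    diag: dict[str, float] = {}
    dialysate: dict[str, list[tuple[float, float]]] = {}
    plasma: dict[str, list[tuple[float, float]]] = {}
    animal_id = ""
    for line, row in rows:
        compartment = row["compartment"].strip()
        name = row["solute"].strip()
        unit = row["unit"].strip()
        where = f"{path}:{line}"
        animal_id = animal_id or row["animal_id"].strip()
        if compartment == "meta":
            if name not in _META_FIELDS:
                raise ParseError(f"{where}: unknown meta field {name!r}")
            value = _parse_float(path, line, row["value"], "value")
            meta[name] = _convert(value, unit, _META_FIELDS[name], where)
        elif compartment == "effluent_diagnostics":
            if name not in _DIAG_FIELDS:
                raise ParseError(f"{where}: unknown diagnostics field {name!r}")
            value = _parse_float(path, line, row["value"], "value")
            diag[name] = _convert(value, unit, _DIAG_FIELDS[name], where)
        elif compartment in ("dialysate", "plasma"):
            if name not in SOLUTES:
                raise ParseError(f"{where}: unknown solute {name!r}")
            value = _parse_float(path, line, row["value"], "value")
            value = _convert(value, unit, _conc_units(name), where)
            time = _parse_float(path, line, row["time_min"], "time_min")
            target = dialysate if compartment == "dialysate" else plasma
            target.setdefault(name, []).append((time, value))
        else:
            raise ParseError(f"{where}: unknown compartment {compartment!r}")

    if "instilled_volume" not in meta:
        raise ParseError(f"{path}: dwell {dwell_id!r} lacks meta instilled_volume")

    dialysate_series = {
        s: SoluteSeries(s, *zip(*sorted(points))) for s, points in dialysate.items()
    }
    plasma_series = {
        s: PlasmaSeries(s, *zip(*sorted(points))) for s, points in plasma.items()
    }
    duration = meta.get("duration", 240.0)
    diagnostics = None
    if diag:
        diagnostics = EffluentDiagnostics(
            culture_positive=None if "culture_positive" not in diag
            else bool(diag["culture_positive"]),
            cloudy_effluent=None if "cloudy_effluent" not in diag
            else bool(diag["cloudy_effluent"]),
            leukocyte_count=diag.get("leukocyte_count"),
            dwell_duration=duration,
        )
    albumin_t0 = None
    alb = dialysate_series.get("albumin")
    if alb is not None and alb.times[0] == 0.0:
        albumin_t0 = alb.dialysate_conc[0]
    return DwellSamples(
        instilled_volume=meta["instilled_volume"],
        duration=duration,
        drain_volume_end=meta.get("drain_volume_end"),
        sample_volume_total=meta.get("sample_volume_total", 0.0),
        albumin_overnight_effluent=meta.get("albumin_overnight_effluent"),
        albumin_t0=albumin_t0,
        albumin_final_drain=meta.get("albumin_final_drain"),
        albumin_flush=meta.get("albumin_flush"),
        flush_volume=meta.get("flush_volume"),
        body_weight=meta.get("body_weight"),
        dialysate=dialysate_series,
        plasma=plasma_series,
        diagnostics=diagnostics,
        dwell_id=dwell_id,
        animal_id=animal_id,
    )


def write_dwell_tables(dwells: Sequence[DwellSamples], path: str | Path) -> None:
    """Write dwells to one tidy delimited table (inverse of the reader)."""
    records = []

    def add(dwell, compartment, solute, time_min, value, unit):
        records.append({
            "dwell_id": dwell.dwell_id, "animal_id": dwell.animal_id,
            "compartment": compartment, "solute": solute,
            "time_min": "" if time_min is None else repr(float(time_min)),
            "value": value if isinstance(value, str) else repr(float(value)),
            "unit": unit,
        })

    for dwell in dwells:
        meta_values = {
            "instilled_volume": (dwell.instilled_volume, "mL"),
            "duration": (dwell.duration, "min"),
            "drain_volume_end": (dwell.drain_volume_end, "mL"),
            "sample_volume_total": (dwell.sample_volume_total, "mL"),
            "flush_volume": (dwell.flush_volume, "mL"),
            "body_weight": (dwell.body_weight, "kg"),
            "albumin_overnight_effluent": (dwell.albumin_overnight_effluent, "g/L"),
            "albumin_final_drain": (dwell.albumin_final_drain, "g/L"),
            "albumin_flush": (dwell.albumin_flush, "g/L"),
        }
        for name, (value, unit) in meta_values.items():
            if value is not None:
                add(dwell, "meta", name, None, value, unit)
        for solute in SOLUTES:
            series = dwell.dialysate.get(solute)
            if series is not None:
                unit = "g/L" if solute in PROTEIN_SOLUTES else "mM"
                for t, c in zip(series.times, series.dialysate_conc):
                    add(dwell, "dialysate", solute, t, c, unit)
            pseries = dwell.plasma.get(solute)
            if pseries is not None:
                unit = "g/L" if solute in PROTEIN_SOLUTES else "mM"
                for t, c in zip(pseries.times, pseries.plasma_conc):
                    add(dwell, "plasma", solute, t, c, unit)
        diag = dwell.diagnostics
        if diag is not None:
            if diag.culture_positive is not None:
                add(dwell, "effluent_diagnostics", "culture_positive", None,
                    float(diag.culture_positive), "bool")
            if diag.cloudy_effluent is not None:
                add(dwell, "effluent_diagnostics", "cloudy_effluent", None,
                    float(diag.cloudy_effluent), "bool")
            if diag.leukocyte_count is not None:
                add(dwell, "effluent_diagnostics", "leukocyte_count", None,
                    diag.leukocyte_count, "10^9/L")

    pd.DataFrame.from_records(records, columns=COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Results and summaries
# ---------------------------------------------------------------------------


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(
    results: Sequence[tuple[SPAResult, str]],
    summaries: Optional[Sequence[StratifiedSummary]],
    outdir: str | Path,
    *,
    config_echo: Optional[dict] = None,
    seed: Optional[int] = None,
) -> dict[str, Path]:
    """Write ``results.json`` (and ``summary.csv`` if summaries given).

    The JSON file records every report with its flags and classification,
    the configuration echo, the package version and the seed, so a run can
    be reproduced exactly.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "spakit_version": __version__,
        "seed": seed,
        "config": config_echo or {},
        "results": [
            {"classification": classification, **result.to_dict()}
            for result, classification in results
        ],
    }
    paths = {"results": outdir / "results.json"}
    with open(paths["results"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    if summaries is not None:
        paths["summary"] = outdir / "summary.csv"
        write_summary(summaries, paths["summary"])
    return paths


def write_summary(summaries: Sequence[StratifiedSummary], path: str | Path) -> None:
    """Write stratified summaries as a delimited parameter x group table."""
    rows = []
    for s in summaries:
        row = asdict(s)
        row["notes"] = ";".join(s.notes)
        rows.append(row)
    pd.DataFrame.from_records(rows).to_csv(path, index=False)


def read_results(path: str | Path) -> tuple[list[tuple[SPAResult, str]], dict]:
    """Read a ``results.json`` back into (report, classification) pairs."""
    with open(path) as fh:
        payload = json.load(fh)
    pairs = []
    for rec in payload.get("results", []):
        rec = dict(rec)
        classification = rec.pop("classification", "indeterminate")
        pairs.append((SPAResult.from_dict(rec), classification))
    meta = {k: v for k, v in payload.items() if k != "results"}
    return pairs, meta


def truth_to_dict(truth) -> dict:
    """JSON-ready view of a simulation truth ledger."""
    d = asdict(truth)
    for key, value in d.items():
        if isinstance(value, np.ndarray):
            d[key] = value.tolist()
        elif isinstance(value, dict):
            d[key] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in value.items()
            }
    return d


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Analysis and simulation settings for a batch run.

    Every field is overridable from a YAML mapping; defaults are the
    package defaults used throughout the analysis layer.
    """

    normalization_bsa: float = 1.73
    bsa_k: float = 0.0734
    bsa_a: float = 0.656
    dp_denominator: str = "t240"
    preset: str = "low_transporter"
    n_dwells: int = 12
    seed: int = 0
    noise_cv: Optional[float] = None
    log_level: str = "INFO"
    simulator_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def analysis_kwargs(self) -> dict:
        return {
            "dp_denominator": self.dp_denominator,
            "bsa_k": self.bsa_k,
            "bsa_a": self.bsa_a,
            "normalization_bsa": self.normalization_bsa,
        }
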