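"""Peritonitis classification and stratified transport summaries.

Peritonitis is called from effluent findings by a 2-of-3 rule: positive
microbial culture, cloudy effluent, and an elevated effluent leukocyte
count (> 0.1 x 10^9/L, valid only for dwells of at least 2 h).  Findings
may be unknown; classification uses three-valued logic with an explicit
``indeterminate`` outcome whenever the unknowns leave the 2-of-3 threshold
undecidable in both directions.

Transport reports are then summarised per parameter and per group
(all / no peritonitis / peritonitis) with mean, SD, median and IQR, the
layout of a classical transport-characteristics table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import MTAC_SOLUTES, SPAError, SPAResult

__all__ = [
    "PERITONITIS",
    "NO_PERITONITIS",
    "INDETERMINATE",
    "LEUKOCYTE_THRESHOLD",
    "LEUKOCYTE_MIN_DWELL",
    "EffluentDiagnostics",
    "StratifiedSummary",
    "classify_peritonitis",
    "default_parameters",
    "result_parameter",
    "group_vectors",
    "stratify_results",
]

PERITONITIS = "peritonitis"
NO_PERITONITIS = "no_peritonitis"
INDETERMINATE = "indeterminate"

#: Effluent leukocyte threshold, 10^9 cells/L.
LEUKOCYTE_THRESHOLD = 0.1
#: Minimum dwell duration (min) for the leukocyte criterion to be assessable.
LEUKOCYTE_MIN_DWELL = 120.0


@dataclass(frozen=True)
class EffluentDiagnostics:
    """Effluent findings of one dwell; ``None`` marks an unknown finding."""

    culture_positive: Optional[bool]
    cloudy_effluent: Optional[bool]
    leukocyte_count: Optional[float]  # 10^9 cells/L
    dwell_duration: float  # minutes

    def __post_init__(self):
        if self.leukocyte_count is not None and self.leukocyte_count < 0:
            raise SPAError("leukocyte count must be non-negative")
        if self.dwell_duration is None or self.dwell_duration <= 0:
            raise SPAError("dwell_duration must be positive")


def _criteria(diag: EffluentDiagnostics) -> tuple[Optional[bool], Optional[bool], Optional[bool]]:
    """Resolve the three case-definition criteria to True/False/unknown."""
    if diag.leukocyte_count is None:
        leuko: Optional[bool] = None
    else:
        leuko = (
            diag.leukocyte_count > LEUKOCYTE_THRESHOLD
            and diag.dwell_duration >= LEUKOCYTE_MIN_DWELL
        )
    return diag.culture_positive, diag.cloudy_effluent, leuko


def classify_peritonitis(diag: EffluentDiagnostics) -> str:
    """Classify one dwell as peritonitis / no_peritonitis / indeterminate.

    Peritonitis requires at least two criteria met.  The leukocyte
    criterion is met only when the count exceeds 0.1 x 10^9/L *and* the
    dwell lasted at least 120 min (a short-dwell count does not satisfy
    it).  Unknown findings yield ``indeterminate`` exactly when both a
    positive and a negative call remain possible.
    """
    crits = _criteria(diag)
    met = sum(1 for c in crits if c is True)
    unknown = sum(1 for c in crits if c is None)
    if met >= 2:
        return PERITONITIS
    if met + unknown < 2:
        return NO_PERITONITIS
    return INDETERMINATE


# ---------------------------------------------------------------------------
# Stratified descriptive summaries
# ---------------------------------------------------------------------------


@dataclass
class StratifiedSummary:
    """Descriptive statistics of one transport parameter in one group.

    ``iqr`` is the interquartile width q75 - q25 (linear-interpolation,
    type-7 quantiles); the quartiles themselves are also reported so a
    median (q25-q75) display can be assembled.  ``sd`` is the n-1 sample
    standard deviation, undefined (None, with a note) for n < 2.
    """

    parameter: str
    group: str
    n: int
    mean: Optional[float] = None
    sd: Optional[float] = None
    median: Optional[float] = None
    iqr: Optional[float] = None
    q25: Optional[float] = None
    q75: Optional[float] = None
    notes: tuple[str, ...] = ()


def default_parameters(normalized: bool = True) -> list[str]:
    """Parameter names summarised by default, mirroring a transport table."""
    params: list[str] = []
    for solute in MTAC_SOLUTES:
        params.append(f"mtac_{solute}")
        if normalized:
            params.append(f"mtac_{solute}_normalized")
    for solute in MTAC_SOLUTES:
        params.append(f"clearance_{solute}")
        if normalized:
            params.append(f"clearance_{solute}_normalized")
    params += ["dp_urea_4h", "dp_creatinine_4h", "dd0_glucose_4h", "ufv_net"]
    return params


def result_parameter(result: SPAResult, name: str) -> Optional[float]:
    """Extract one named parameter from a transport report (None if absent)."""
    if name in ("ufv_net", "dp_urea_4h", "dp_creatinine_4h", "dd0_glucose_4h",
                "rv_pre", "rv_post", "bsa"):
        return getattr(result, name)
    for prefix, attr in (("mtac_", "mtac"), ("clearance_", "clearance")):
        if name.startswith(prefix):
            solute = name[len(prefix):]
            suffix = ""
            if solute.endswith("_normalized"):
                solute = solute[: -len("_normalized")]
                suffix = "_normalized"
            rec = result.solutes.get(solute)
            if rec is None:
                return None
            return getattr(rec, attr + suffix)
    raise SPAError(f"unknown parameter {name!r}")


def group_vectors(
    results: Sequence[tuple[SPAResult, str]], parameter: str
) -> dict[str, np.ndarray]:
    """Non-missing values of one parameter per group.

    The ``all`` group contains every classified dwell (indeterminate
    included); the two named groups partition the determinate dwells.
    """
    groups: dict[str, list[float]] = {"all": [], NO_PERITONITIS: [], PERITONITIS: []}
    for result, classification in results:
        value = result_parameter(result, parameter)
        if value is None or not math.isfinite(value):
            continue
        groups["all"].append(value)
        if classification in (NO_PERITONITIS, PERITONITIS):
            groups[classification].append(value)
    return {g: np.asarray(v, dtype=float) for g, v in groups.items()}


def _summarise(parameter: str, group: str, values: np.ndarray) -> StratifiedSummary:
    n = int(values.size)
    if n == 0:
        return StratifiedSummary(parameter, group, 0, notes=("no data",))
    notes: tuple[str, ...] = ()
    if n >= 2:
        sd = float(np.std(values, ddof=1))
    else:
        sd = None
        notes = ("sd undefined for n = 1",)
    q25, q50, q75 = (float(q) for q in np.quantile(values, [0.25, 0.5, 0.75]))
    return StratifiedSummary(
        parameter, group, n,
        mean=float(np.mean(values)), sd=sd,
        median=q50, iqr=q75 - q25, q25=q25, q75=q75,
        notes=notes,
    )


def stratify_results(
    results: Sequence[tuple[SPAResult, str]],
    parameters: Optional[Sequence[str]] = None,
) -> list[StratifiedSummary]:
    """Summarise transport parameters for all / no-peritonitis / peritonitis.

    ``results`` pairs each report with its classification string.  Both
    mean +/- SD and median (IQR) are always produced; choosing which to
    display is a presentation decision left to the caller.
    """
    if len(results) == 0:
        raise SPAError("no results to stratify")
    if parameters is None:
        normalized = any(
            rec.mtac_normalized is not None
            for result, _ in results
            for rec in result.solutes.values()
        )
        parameters = default_parameters(normalized=normalized)
    out: list[StratifiedSummary] = []
    for parameter in parameters:
        vectors = group_vectors(results, parameter)
        for group in ("all", NO_PERITONITIS, PERITONITIS):
            out.append(_summarise(parameter, group, vectors[group]))
    return out
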