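"""Transport-parameter calculations for a standard peritoneal permeability
assessment (SPA).

A SPA is a standardized peritoneal dialysis dwell — here 2 L of 1.36 %
glucose dialysate left in the peritoneal cavity for 4 h — with timed
dialysate sampling and plasma sampling at 0, 120 and 240 min.  From one
dwell's measurements this module derives the classical transport report:

* residual volume before and after the dwell, by indicator dilution of
  endogenous albumin between the overnight effluent (or end-dwell drain)
  and the freshly mixed dialysate (or flush),
* net ultrafiltration volume from the volume ledger of the dwell,
* the mass transfer area coefficient (MTAC) of urea, creatinine,
  phosphate and potassium with the simplified Garred log-ratio formula,
* total solute removal and clearance,
* D/P ratios at 4 h for urea and creatinine, D/D0 for glucose,
* body-surface-area normalization (x 1.73 / BSA) of MTAC and clearance.

Internal units are fixed: minutes, mL, mM for small solutes and g/L for
proteins, so that concentration x volume is µmol (respectively mg) and
amounts are reported in mmol (respectively g).  Unit conversion belongs to
the I/O layer (:mod:`spakit.io`).

Per-solute computability problems (indicator-dilution failure, plasma/
dialysate gradient crossover, missing samples) are reported as *flags* on
the result, never silently dropped or clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SMALL_SOLUTES",
    "PROTEIN_SOLUTES",
    "SOLUTES",
    "MTAC_SOLUTES",
    "PLASMA_TIMES",
    "SPAError",
    "IndicatorDilutionError",
    "GradientCrossoverError",
    "MissingDataError",
    "SoluteSeries",
    "PlasmaSeries",
    "DwellSamples",
    "SoluteTransport",
    "SPAResult",
    "residual_volume",
    "net_ultrafiltration",
    "mtac_garred",
    "total_solute_removal",
    "clearance",
    "mean_plasma",
    "dp_ratio",
    "dd0_ratio",
    "body_surface_area",
    "analyze_spa",
    "analyze_batch",
]

#: Solutes measured in mM.
SMALL_SOLUTES = ("urea", "creatinine", "phosphate", "potassium", "sodium", "glucose")
#: Solutes measured in g/L.
PROTEIN_SOLUTES = ("albumin", "total_protein")
SOLUTES = SMALL_SOLUTES + PROTEIN_SOLUTES
#: Solutes for which MTAC / TSR / clearance are computed by default.
MTAC_SOLUTES = ("urea", "creatinine", "phosphate", "potassium")
#: Scheduled venous sampling times of the assessment, minutes.
PLASMA_TIMES = (0.0, 120.0, 240.0)

#: Default porcine body-surface-area power law BSA = k * W^a (m^2, W in kg).
BSA_K_DEFAULT = 0.0734
BSA_A_DEFAULT = 0.656
#: Reference surface area for normalization, m^2.
BSA_REFERENCE = 1.73


class SPAError(ValueError):
    """Base class for SPA computability errors."""


class IndicatorDilutionError(SPAError):
    """Marker not more concentrated in residual fluid than in mixed fluid."""


class GradientCrossoverError(SPAError):
    """Plasma-dialysate gradient changed sign during the dwell."""


class MissingDataError(SPAError):
    """A required measurement is absent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SoluteSeries:
    """Timed dialysate concentrations of one solute during a dwell.

    times are minutes since instillation, strictly increasing from 0;
    concentrations are mM (small solutes) or g/L (proteins).
    """

    solute: str
    times: tuple[float, ...]
    dialysate_conc: tuple[float, ...]

    def __post_init__(self):
        if self.solute not in SOLUTES:
            raise SPAError(f"unknown solute {self.solute!r}")
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.dialysate_conc, dtype=float)
        if t.size != c.size:
            raise SPAError(f"{self.solute}: times and concentrations differ in length")
        if t.size == 0 or t[0] != 0.0:
            raise SPAError(f"{self.solute}: series must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise SPAError(f"{self.solute}: times must be strictly increasing")
        if np.any(c < 0):
            raise SPAError(f"{self.solute}: negative dialysate concentration")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "dialysate_conc", tuple(float(x) for x in c))

    def at(self, time: float, *, atol: float = 1e-6) -> float:
        """Concentration at an exact scheduled time; raises if not sampled."""
        for t, c in zip(self.times, self.dialysate_conc):
            if abs(t - time) <= atol:
                return c
        raise MissingDataError(f"{self.solute}: no dialysate sample at t = {time:g} min")


@dataclass(frozen=True)
class PlasmaSeries:
    """Plasma concentrations of one solute at (a subset of) 0/120/240 min.

    Missing scheduled draws may be encoded as NaN or simply omitted.
    """

    solute: str
    times: tuple[float, ...]
    plasma_conc: tuple[float, ...]

    def __post_init__(self):
        if self.solute not in SOLUTES:
            raise SPAError(f"unknown solute {self.solute!r}")
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.plasma_conc, dtype=float)
        if t.size != c.size:
            raise SPAError(f"{self.solute}: times and concentrations differ in length")
        for x in t:
            if not any(abs(x - s) <= 1e-6 for s in PLASMA_TIMES):
                raise SPAError(
                    f"{self.solute}: plasma time {x:g} not in scheduled {PLASMA_TIMES}"
                )
        finite = c[np.isfinite(c)]
        if finite.size == 0:
            raise SPAError(f"{self.solute}: all plasma values missing")
        if np.any(finite < 0):
            raise SPAError(f"{self.solute}: negative plasma concentration")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "plasma_conc", tuple(float(x) for x in c))

    def scheduled(self) -> tuple[float, float, float]:
        """Values at 0/120/240 min with NaN where missing."""
        out = [math.nan] * 3
        for t, c in zip(self.times, self.plasma_conc):
            for i, s in enumerate(PLASMA_TIMES):
                if abs(t - s) <= 1e-6:
                    out[i] = c
        return tuple(out)  # type: ignore[return-value]


@dataclass
class DwellSamples:
    """All measurements of one SPA dwell, in internal units.

    Volumes are mL, duration minutes, albumin markers g/L.  ``flush_volume``
    defaults to the instilled volume (a fresh bag is used for the flush).
    Optional fields left ``None`` restrict what :func:`analyze_spa` can
    compute; the result carries flags for everything that was skipped.
    """

    instilled_volume: float
    duration: float = 240.0
    drain_volume_end: Optional[float] = None
    sample_volume_total: float = 0.0
    albumin_overnight_effluent: Optional[float] = None
    albumin_t0: Optional[float] = None
    albumin_final_drain: Optional[float] = None
    albumin_flush: Optional[float] = None
    flush_volume: Optional[float] = None
    body_weight: Optional[float] = None
    dialysate: dict[str, SoluteSeries] = field(default_factory=dict)
    plasma: dict[str, PlasmaSeries] = field(default_factory=dict)
    diagnostics: Optional["object"] = None  # EffluentDiagnostics, if collected
    dwell_id: str = "dwell"
    animal_id: str = ""

    def __post_init__(self):
        if self.instilled_volume <= 0:
            raise SPAError("instilled_volume must be positive")
        if self.duration <= 0:
            raise SPAError("duration must be positive")
        if not (0 <= self.sample_volume_total < self.instilled_volume):
            raise SPAError("sample_volume_total must be in [0, instilled_volume)")
        if self.flush_volume is None:
            self.flush_volume = self.instilled_volume


@dataclass
class SoluteTransport:
    """Per-solute derived transport parameters (None = not computable)."""

    mtac: Optional[float] = None
    mtac_normalized: Optional[float] = None
    tsr: Optional[float] = None
    clearance: Optional[float] = None
    clearance_normalized: Optional[float] = None


@dataclass
class SPAResult:
    """Complete transport report for one dwell.

    MTAC and clearance in mL/min (normalized: mL/min/1.73 m^2), TSR in mmol
    (g for proteins), volumes in mL, ratios dimensionless.  ``flags`` maps a
    parameter or solute name to human-readable computability notes.
    """

    dwell_id: str = "dwell"
    animal_id: str = ""
    rv_pre: Optional[float] = None
    rv_post: Optional[float] = None
    ufv_net: Optional[float] = None
    bsa: Optional[float] = None
    solutes: dict[str, SoluteTransport] = field(default_factory=dict)
    dp_urea_4h: Optional[float] = None
    dp_creatinine_4h: Optional[float] = None
    dd0_glucose_4h: Optional[float] = None
    flags: dict[str, list[str]] = field(default_factory=dict)

    def add_flag(self, key: str, note: str) -> None:
        self.flags.setdefault(key, []).append(note)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SPAResult":
        d = dict(d)
        d["solutes"] = {
            s: SoluteTransport(**rec) for s, rec in d.get("solutes", {}).items()
        }
        d["flags"] = {k: list(v) for k, v in d.get("flags", {}).items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def residual_volume(v_in: float, c_t0: float, c_drain: float) -> float:
    """Residual volume by indicator dilution of albumin.

    The fluid left behind after a drain (concentration ``c_drain`` of the
    marker) mixes with ``v_in`` mL of marker-free fresh dialysate; the mixed
    concentration ``c_t0`` then identifies the residual volume:

        RV = v_in * c_t0 / (c_drain - c_t0)

    Raises :class:`IndicatorDilutionError` when ``c_drain <= c_t0`` — the
    marker must be strictly more concentrated in the residual fluid than in
    the mixture, otherwise the measurement failed.
    """
    if v_in <= 0:
        raise SPAError("v_in must be positive")
    if c_t0 < 0 or c_drain < 0:
        raise SPAError("marker concentrations must be non-negative")
    if c_drain <= c_t0:
        raise IndicatorDilutionError(
            f"marker dilution failed: c_drain ({c_drain:g}) <= c_t0 ({c_t0:g})"
        )
    return v_in * c_t0 / (c_drain - c_t0)


def net_ultrafiltration(v_t240: float, rv_t240: float, v_sample: float, v_t0: float) -> float:
    """Net effective ultrafiltration volume over the dwell (mL).

    UFV = end drain + end residual + sampled-out volume - start volume.
    Negative values mean net fluid absorption (typical during peritonitis).
    """
    for name, v in (("v_t240", v_t240), ("rv_t240", rv_t240),
                    ("v_sample", v_sample), ("v_t0", v_t0)):
        if v < 0:
            raise SPAError(f"{name} must be non-negative")
    return v_t240 + rv_t240 + v_sample - v_t0


def mtac_garred(v_0: float, v_t: float, t: float, d_0: float, d_t: float, p: float) -> float:
    """Mass transfer area coefficient by the simplified Garred formula (mL/min).

    MTAC = (v_t / t) * ln( v_0 * (p - d_0) / (v_t * (p - d_t)) )

    with ``v_0`` the instilled volume, ``v_t`` the drained volume at the end
    of the dwell, ``d_0``/``d_t`` the dialysate concentrations at start/end
    and ``p`` the mean plasma concentration.  The MTAC is the theoretical
    maximal diffusive clearance, reached while the dialysate concentration
    is still zero.  Valid on either side of the gradient (for glucose both
    differences are negative and the log argument stays positive); a sign
    change of (p - d) during the dwell violates the underlying single-pool
    diffusion model and raises :class:`GradientCrossoverError`.
    """
    if v_0 <= 0 or v_t <= 0 or t <= 0:
        raise SPAError("volumes and time must be positive")
    g0 = p - d_0
    gt = p - d_t
    if g0 == 0.0 or gt == 0.0 or (g0 > 0) != (gt > 0):
        raise GradientCrossoverError(
            f"plasma-dialysate gradient crossed zero during the dwell "
            f"(P-D0 = {g0:g}, P-Dt = {gt:g})"
        )
    return (v_t / t) * math.log((v_0 * g0) / (v_t * gt))


def total_solute_removal(c_t: float, v_t: float, c_0: float, v_0: float) -> float:
    """Total solute removal over the dwell: c_t*v_t - c_0*v_0.

    Concentrations in mM (g/L for proteins) and volumes in mL give TSR in
    mmol (g); here v are *intraperitoneal* volumes including residual fluid.
    Negative values are legitimate — glucose is absorbed from the cavity.
    """
    if v_t <= 0 or v_0 <= 0:
        raise SPAError("volumes must be positive")
    if c_t < 0 or c_0 < 0:
        raise SPAError("concentrations must be non-negative")
    return (c_t * v_t - c_0 * v_0) / 1000.0


def clearance(tsr: float, c_av: float, t: float) -> float:
    """Clearance rate TSR / (C_av * t), in mL/min.

    ``tsr`` in mmol (g), ``c_av`` the mean plasma concentration in mM (g/L),
    ``t`` in minutes; mmol / (mmol/L * min) = L/min, returned as mL/min.
    """
    if t <= 0:
        raise SPAError("t must be positive")
    if c_av <= 0:
        raise MissingDataError("clearance undefined for zero mean plasma concentration")
    return 1000.0 * tsr / (c_av * t)


def _plasma_profile(series: PlasmaSeries) -> tuple[list[float], list[str]]:
    """Fill the 0/120/240 plasma triple; returns (values, imputation notes).

    A single missing interior point (120 min) is linearly interpolated
    between its neighbours; a missing endpoint is carried from the nearest
    available draw.  Every imputation is reported.
    """
    p0, p120, p240 = series.scheduled()
    notes: list[str] = []
    if math.isnan(p120) and not math.isnan(p0) and not math.isnan(p240):
        p120 = 0.5 * (p0 + p240)
        notes.append("plasma at 120 min linearly interpolated")
    if math.isnan(p0):
        p0 = p120 if not math.isnan(p120) else p240
        notes.append("plasma at 0 min carried from nearest draw")
    if math.isnan(p240):
        p240 = p120 if not math.isnan(p120) else p0
        notes.append("plasma at 240 min carried from nearest draw")
    if math.isnan(p120):  # only endpoints or a single endpoint present
        p120 = 0.5 * (p0 + p240)
        notes.append("plasma at 120 min linearly interpolated")
    return [p0, p120, p240], notes


def mean_plasma(series: PlasmaSeries) -> float:
    """Arithmetic mean of the 0/120/240 min plasma values after imputation."""
    values, _ = _plasma_profile(series)
    return sum(values) / 3.0


def dp_ratio(dialysate_4h: float, plasma_4h: float) -> float:
    """Dialysate-to-plasma concentration ratio at the end of the dwell."""
    if plasma_4h <= 0:
        raise MissingDataError("D/P undefined for zero plasma concentration")
    if dialysate_4h < 0:
        raise SPAError("dialysate concentration must be non-negative")
    return dialysate_4h / plasma_4h


def dd0_ratio(glucose_4h: float, glucose_0h: float) -> float:
    """End-to-start dialysate glucose ratio (lower = faster transport)."""
    if glucose_0h <= 0:
        raise MissingDataError("D/D0 undefined for zero initial glucose")
    if glucose_4h < 0:
        raise SPAError("glucose concentration must be non-negative")
    return glucose_4h / glucose_0h


def body_surface_area(weight: float, k: float = BSA_K_DEFAULT, a: float = BSA_A_DEFAULT) -> float:
    """Body surface area (m^2) from weight (kg) by a power law k * W^a.

    Defaults are the porcine coefficients; both are configurable for other
    species or alternative published fits.
    """
    if weight <= 0:
        raise SPAError("weight must be positive")
    return k * weight**a


# ---------------------------------------------------------------------------
# Whole-dwell orchestration
# ---------------------------------------------------------------------------


def analyze_spa(
    dwell: DwellSamples,
    *,
    dp_denominator: str = "t240",
    bsa_k: float = BSA_K_DEFAULT,
    bsa_a: float = BSA_A_DEFAULT,
    normalization_bsa: float = BSA_REFERENCE,
    mtac_solutes: Sequence[str] = MTAC_SOLUTES,
) -> SPAResult:
    """Compute the full transport report for one dwell.

    dp_denominator selects the plasma value for D/P ratios: ``"t240"``
    (default, the draw at the end of the dwell) or ``"mean"`` (the same
    0/120/240 mean used for MTAC).  Solutes whose inputs are missing or
    whose gradient crossed zero are flagged and left None, never dropped.
    """
    if dp_denominator not in ("t240", "mean"):
        raise SPAError(f"unknown dp_denominator policy {dp_denominator!r}")
    res = SPAResult(dwell_id=dwell.dwell_id, animal_id=dwell.animal_id)

    # Residual volume before the dwell (overnight effluent vs t0 mixture).
    if dwell.albumin_overnight_effluent is None or dwell.albumin_t0 is None:
        res.add_flag("rv_pre", "missing albumin marker measurement")
    else:
        try:
            res.rv_pre = residual_volume(
                dwell.instilled_volume, dwell.albumin_t0, dwell.albumin_overnight_effluent
            )
        except SPAError as err:
            res.add_flag("rv_pre", str(err))

    # Residual volume after the complete drain (end drain vs flush).
    if dwell.albumin_final_drain is None or dwell.albumin_flush is None:
        res.add_flag("rv_post", "missing albumin marker measurement")
    else:
        try:
            res.rv_post = residual_volume(
                dwell.flush_volume, dwell.albumin_flush, dwell.albumin_final_drain
            )
        except SPAError as err:
            res.add_flag("rv_post", str(err))

    # Net ultrafiltration needs both residual volumes and the end drain.
    if dwell.drain_volume_end is None:
        res.add_flag("ufv_net", "missing end-of-dwell drain volume")
    elif res.rv_pre is None or res.rv_post is None:
        res.add_flag("ufv_net", "not computable without both residual volumes")
    else:
        res.ufv_net = net_ultrafiltration(
            dwell.drain_volume_end,
            res.rv_post,
            dwell.sample_volume_total,
            dwell.instilled_volume + res.rv_pre,
        )

    if dwell.body_weight is not None:
        res.bsa = body_surface_area(dwell.body_weight, bsa_k, bsa_a)
    norm = (normalization_bsa / res.bsa) if res.bsa else None

    for solute in mtac_solutes:
        rec = SoluteTransport()
        res.solutes[solute] = rec
        series = dwell.dialysate.get(solute)
        if series is None:
            res.add_flag(solute, "no dialysate series")
            continue
        plasma = dwell.plasma.get(solute)
        if plasma is None:
            res.add_flag(solute, "no plasma series; MTAC/clearance not computable")
            continue
        p_values, p_notes = _plasma_profile(plasma)
        for note in p_notes:
            res.add_flag(solute, note)
        p_mean = sum(p_values) / 3.0
        try:
            d_0 = series.at(0.0)
            d_t = series.at(dwell.duration)
        except MissingDataError as err:
            res.add_flag(solute, str(err))
            continue

        if dwell.drain_volume_end is None:
            res.add_flag(solute, "MTAC not computable without end drain volume")
        else:
            try:
                rec.mtac = mtac_garred(
                    dwell.instilled_volume, dwell.drain_volume_end,
                    dwell.duration, d_0, d_t, p_mean,
                )
            except SPAError as err:
                res.add_flag(solute, str(err))

        if res.rv_pre is None or res.rv_post is None or dwell.drain_volume_end is None:
            res.add_flag(solute, "TSR/clearance not computable without volume ledger")
        else:
            rec.tsr = total_solute_removal(
                d_t, dwell.drain_volume_end + res.rv_post,
                d_0, dwell.instilled_volume + res.rv_pre,
            )
            try:
                rec.clearance = clearance(rec.tsr, p_mean, dwell.duration)
            except SPAError as err:
                res.add_flag(solute, str(err))

        if norm is not None:
            if rec.mtac is not None:
                rec.mtac_normalized = rec.mtac * norm
            if rec.clearance is not None:
                rec.clearance_normalized = rec.clearance * norm

    # 4 h concentration ratios.
    for solute, attr in (("urea", "dp_urea_4h"), ("creatinine", "dp_creatinine_4h")):
        series = dwell.dialysate.get(solute)
        plasma = dwell.plasma.get(solute)
        if series is None or plasma is None:
            res.add_flag(attr, "missing dialysate or plasma series")
            continue
        try:
            d_4h = series.at(dwell.duration)
            if dp_denominator == "mean":
                p_ref = mean_plasma(plasma)
            else:
                p_ref = _plasma_profile(plasma)[0][2]
            setattr(res, attr, dp_ratio(d_4h, p_ref))
        except SPAError as err:
            res.add_flag(attr, str(err))

    glucose = dwell.dialysate.get("glucose")
    if glucose is None:
        res.add_flag("dd0_glucose_4h", "missing dialysate glucose series")
    else:
        try:
            res.dd0_glucose_4h = dd0_ratio(glucose.at(dwell.duration), glucose.at(0.0))
        except SPAError as err:
            res.add_flag("dd0_glucose_4h", str(err))

    return res


def analyze_batch(dwells: Sequence[DwellSamples], **kwargs) -> list[SPAResult]:
    """Analyze several dwells independently, preserving input order."""
    return [analyze_spa(d, **kwargs) for d in dwells]
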