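"""Seeded synthetic-data generator for SPA dwells and uremia trajectories.

The dwell generator integrates, per solute, a two-pool kinetic model

    d(V D)/dt = MTAC (P - D) + S Qu(t) P - L D
    dV/dt     = Qu(t) - L,      Qu(t) = q0 exp(-t / tau)

where ``P`` is the (constant within a dwell) plasma concentration, ``D``
the dialysate concentration, ``MTAC`` the diffusive mass transfer area
coefficient, ``S`` the sieving coefficient of the convective
(ultrafiltration) flux ``Qu`` and ``L`` a constant lymphatic absorption
flow removing fluid at dialysate composition.  Scheduled samples remove a
small aliquot instantaneously at unchanged concentration.  In the
diffusive limit (no ultrafiltration, lymphatics, or sampling, constant
volume) the model collapses to the closed form

    D(t) = P + (D0 - P) exp(-MTAC t / V)

which is exactly the assumption of the Garred estimator: the estimator is
exact on that limit, and carries a small, reproducible bias once
convection and lymphatic flow are switched on.

Every simulation carries a *truth ledger* — generating parameters,
integrated flows and transported masses — side by side with, but never
mixed into, the noisy observables.  Measurement noise is multiplicative
Gaussian (CV-parameterised, truncated at zero) on measured concentrations
only.  Identical configs and seeds yield identical outputs.

The uremia generator produces a smooth plasma-solute trajectory rising
from a stable chronic-kidney-disease baseline to an acute-on-chronic peak
(aminoglycoside-type injury) followed by slow exponential recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .core import (
    PLASMA_TIMES,
    SOLUTES,
    DwellSamples,
    PlasmaSeries,
    SoluteSeries,
    SPAError,
)
from .diagnostics import EffluentDiagnostics

__all__ = [
    "SimulationError",
    "SimulationConfig",
    "DwellTruth",
    "SimulatedDwell",
    "UremiaCourse",
    "UREMIA_DEFAULTS",
    "constant_volume_dialysate",
    "simulate_overnight",
    "simulate_dwell",
    "simulate_batch",
    "simulate_uremia_course",
    "scenario_preset",
]

#: ODE solver tolerances; balance identities hold to ~1e-8 relative.
_RTOL = 1e-11
_ATOL = 1e-9

#: Solutes measured in venous blood during the assessment (glucose is not).
_PLASMA_MEASURED = ("urea", "creatinine", "phosphate", "potassium", "sodium",
                    "albumin", "total_protein")


class SimulationError(RuntimeError):
    """Pathological configuration detected during integration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth kinetic parameters and noise model for one dwell.

    Units: mL, min, mM (g/L for albumin / total protein), mL/min for rates.
    Defaults describe a 2 L, 4 h, 1.36 %-glucose dwell in a ~60 kg uremic
    pig at the acute-on-chronic uremia peak, preceded by an overnight
    dwell that leaves a 300 mL residual volume.
    """

    true_mtac: Mapping[str, float] = field(default_factory=lambda: {
        "urea": 8.3, "creatinine": 3.3, "phosphate": 2.3, "potassium": 18.6,
        "sodium": 2.0, "glucose": 4.0, "albumin": 0.05, "total_protein": 0.04,
    })
    plasma_level: Mapping[str, float] = field(default_factory=lambda: {
        "urea": 16.7, "creatinine": 0.932, "phosphate": 2.6, "potassium": 4.4,
        "sodium": 140.0, "glucose": 5.0, "albumin": 30.0, "total_protein": 55.0,
    })
    sieving_coefficient: Mapping[str, float] = field(default_factory=lambda: {
        "urea": 0.6, "creatinine": 0.6, "phosphate": 0.6, "potassium": 0.6,
        "sodium": 0.6, "glucose": 0.6, "albumin": 0.1, "total_protein": 0.1,
    })
    initial_dialysate: Mapping[str, float] = field(default_factory=lambda: {
        "glucose": 75.0, "sodium": 132.0,
    })
    instilled_volume: float = 2000.0
    residual_volume_true: float = 300.0
    residual_albumin: float = 2.3
    overnight_duration: float = 480.0
    uf_rate_initial: float = 3.8
    uf_decay_time: float = 90.0
    lymphatic_rate: float = 0.5
    sample_times: tuple[float, ...] = (0.0, 10.0, 30.0, 60.0, 120.0, 180.0, 240.0)
    sample_retained_volume: float = 5.0
    flush_volume: float = 2000.0
    noise_cv: float = 0.05
    body_weight: float = 60.0
    peritonitis: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("instilled_volume", "overnight_duration", "flush_volume",
                     "uf_decay_time", "body_weight"):
            if getattr(self, name) <= 0:
                raise SPAError(f"{name} must be positive")
        for name in ("residual_volume_true", "residual_albumin", "uf_rate_initial",
                     "lymphatic_rate", "sample_retained_volume", "noise_cv"):
            if getattr(self, name) < 0:
                raise SPAError(f"{name} must be non-negative")
        t = np.asarray(self.sample_times, dtype=float)
        if t.size < 2 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise SPAError("sample_times must be strictly increasing and start at 0")
        for s, v in self.sieving_coefficient.items():
            if not 0.0 <= v <= 1.0:
                raise SPAError(f"sieving coefficient of {s} outside [0, 1]")
        for s in self.true_mtac:
            if self.true_mtac[s] < 0:
                raise SPAError(f"negative MTAC for {s}")
            if s not in SOLUTES:
                raise SPAError(f"unknown solute {s!r}")

    @property
    def duration(self) -> float:
        return float(self.sample_times[-1])

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("true_mtac", "plasma_level", "sieving_coefficient",
                    "initial_dialysate"):
            d[key] = dict(d[key])
        d["sample_times"] = list(d["sample_times"])
        return d


@dataclass
class DwellTruth:
    """Ground-truth side channel of one simulated dwell (noise-free)."""

    mtac: dict[str, float]
    rv_pre: float
    rv_post: float
    integrated_uf: float
    integrated_lymph_volume: float
    sampled_volume: float
    initial_volume: float
    final_volume: float
    volume_times: np.ndarray  # post-sampling volumes at sample times
    volume_trajectory: np.ndarray
    dialysate_conc: dict[str, np.ndarray]  # true concentrations at sample times
    initial_mass: dict[str, float]  # µmol (mg for proteins), at t0 pre-sampling
    final_mass: dict[str, float]
    diffusive_mass_in: dict[str, float]
    convective_mass_in: dict[str, float]
    lymphatic_mass_out: dict[str, float]
    sampled_mass: dict[str, float]

    def transported_mass(self, solute: str) -> float:
        """Net mass moved into the dialysate across the membrane (µmol/mg)."""
        return (
            self.diffusive_mass_in[solute]
            + self.convective_mass_in[solute]
            - self.lymphatic_mass_out[solute]
        )


@dataclass
class SimulatedDwell:
    """Noisy observables plus the truth ledger of one simulated dwell."""

    observables: DwellSamples
    truth: DwellTruth
    config: SimulationConfig


def constant_volume_dialysate(t: float, mtac: float, volume: float,
                              plasma: float, d0: float = 0.0) -> float:
    """Closed-form dialysate concentration of the pure-diffusion limit."""
    return plasma + (d0 - plasma) * math.exp(-mtac * t / volume)


# ---------------------------------------------------------------------------
# Overnight dwell
# ---------------------------------------------------------------------------


def _overnight_composition(config: SimulationConfig) -> dict[str, float]:
    """Residual-fluid solute concentrations left by the overnight dwell.

    Small solutes approach plasma by the constant-volume diffusion closed
    form over the overnight duration; protein concentrations are set by
    ``residual_albumin`` directly (overnight effluent protein reflects
    cumulative leak rather than the dwell-scale MTAC).
    """
    volume = config.instilled_volume + config.residual_volume_true
    out: dict[str, float] = {}
    for solute in SOLUTES:
        if solute == "albumin":
            out[solute] = config.residual_albumin
        elif solute == "total_protein":
            out[solute] = 1.6 * config.residual_albumin
        else:
            p = config.plasma_level.get(solute, 0.0)
            d_fresh = config.initial_dialysate.get(solute, 0.0)
            out[solute] = constant_volume_dialysate(
                config.overnight_duration, config.true_mtac.get(solute, 0.0),
                volume, p, d_fresh,
            )
    return out


def simulate_overnight(config: SimulationConfig) -> tuple[float, float]:
    """Residual volume and effluent albumin left by the overnight dwell.

    The effluent albumin concentration strictly exceeds the t0 albumin of
    the following fresh dwell implied by mixing, so the indicator-dilution
    inversion is well-posed on synthetic data whenever the residual volume
    is nonzero.
    """
    return config.residual_volume_true, config.residual_albumin


# ---------------------------------------------------------------------------
# Dwell integration
# ---------------------------------------------------------------------------


def _integrate_dwell(config: SimulationConfig):
    """Integrate the two-pool model over the dwell with sampling events.

    State vector: [V, M_1..M_k, Idiff_1..k, Ilymph_1..k] with masses in
    µmol (mg for proteins) and cumulative diffusive in-flux / lymphatic
    out-flux integrals per solute.  Samples are removed instantaneously at
    the scheduled times; truth concentrations are recorded pre-removal
    (removal does not change concentration).
    """
    solutes = list(SOLUTES)
    k = len(solutes)
    mtac = np.array([config.true_mtac.get(s, 0.0) for s in solutes])
    plasma = np.array([config.plasma_level.get(s, 0.0) for s in solutes])
    sieving = np.array([config.sieving_coefficient.get(s, 0.0) for s in solutes])
    q0, tau, lymph = config.uf_rate_initial, config.uf_decay_time, config.lymphatic_rate

    rv = config.residual_volume_true
    residual = _overnight_composition(config)
    v0 = config.instilled_volume + rv
    d_init = np.array([
        (config.instilled_volume * config.initial_dialysate.get(s, 0.0)
         + rv * residual[s]) / v0
        for s in solutes
    ])

    def rhs(t, y):
        v = y[0]
        d = y[1:1 + k] / v
        qu = q0 * math.exp(-t / tau)
        diff = mtac * (plasma - d)
        lym = lymph * d
        dy = np.empty_like(y)
        dy[0] = qu - lymph
        dy[1:1 + k] = diff + sieving * qu * plasma - lym
        dy[1 + k:1 + 2 * k] = diff
        dy[1 + 2 * k:] = lym
        return dy

    def depleted(t, y):
        return y[0] - 1.0  # abort if < 1 mL of fluid remains

    depleted.terminal = True  # type: ignore[attr-defined]
    depleted.direction = -1  # type: ignore[attr-defined]

    y = np.zeros(1 + 3 * k)
    y[0] = v0
    y[1:1 + k] = d_init * v0

    times = [float(t) for t in config.sample_times]
    vs = config.sample_retained_volume
    conc_truth = {s: [] for s in solutes}
    volume_post = []
    sampled_mass = np.zeros(k)
    sampled_volume = 0.0
    for i, t_now in enumerate(times):
        d_now = y[1:1 + k] / y[0]
        for j, s in enumerate(solutes):
            conc_truth[s].append(d_now[j])
        if vs > 0:
            if y[0] - vs <= 1.0:
                raise SimulationError(
                    f"sampling at t = {t_now:g} min would deplete the cavity"
                )
            y[0] -= vs
            y[1:1 + k] -= vs * d_now
            sampled_mass += vs * d_now
            sampled_volume += vs
        volume_post.append(y[0])
        if i == len(times) - 1:
            break
        sol = solve_ivp(
            rhs, (t_now, times[i + 1]), y, method="DOP853",
            rtol=_RTOL, atol=_ATOL, events=depleted, dense_output=False,
        )
        if not sol.success or sol.status == 1:
            raise SimulationError(
                f"intraperitoneal volume depleted between t = {t_now:g} and "
                f"{times[i + 1]:g} min (ultrafiltration/lymphatic config is "
                "pathological)"
            )
        y = sol.y[:, -1]

    duration = times[-1]
    integrated_uf = q0 * tau * (1.0 - math.exp(-duration / tau))
    truth = DwellTruth(
        mtac={s: float(m) for s, m in zip(solutes, mtac)},
        rv_pre=rv,
        rv_post=rv,
        integrated_uf=integrated_uf,
        integrated_lymph_volume=lymph * duration,
        sampled_volume=sampled_volume,
        initial_volume=v0,
        final_volume=float(y[0]),
        volume_times=np.asarray(times),
        volume_trajectory=np.asarray(volume_post),
        dialysate_conc={s: np.asarray(v) for s, v in conc_truth.items()},
        initial_mass={s: float(d_init[j] * v0) for j, s in enumerate(solutes)},
        final_mass={s: float(y[1 + j]) for j, s in enumerate(solutes)},
        diffusive_mass_in={s: float(y[1 + k + j]) for j, s in enumerate(solutes)},
        convective_mass_in={
            s: float(sieving[j] * plasma[j] * integrated_uf)
            for j, s in enumerate(solutes)
        },
        lymphatic_mass_out={s: float(y[1 + 2 * k + j]) for j, s in enumerate(solutes)},
        sampled_mass={s: float(sampled_mass[j]) for j, s in enumerate(solutes)},
    )
    return truth


def _noisy(rng: np.random.Generator, value: float, cv: float) -> float:
    """Multiplicative Gaussian measurement noise, truncated at zero."""
    if cv == 0.0:
        return float(value)
    return float(value * max(0.0, 1.0 + cv * rng.standard_normal()))


def simulate_dwell(config: SimulationConfig) -> SimulatedDwell:
    """Simulate one SPA dwell: integrate truth, then measure with noise.

    The complete end drain leaves ``residual_volume_true`` behind again
    (same cavity and catheter as before the dwell); the cavity is then
    flushed with a fresh bag to measure the post-dwell residual volume by
    albumin dilution.  Raises :class:`SimulationError` if the configured
    flows drive the intraperitoneal volume to depletion.
    """
    truth = _integrate_dwell(config)
    rng = np.random.default_rng(config.seed)
    cv = config.noise_cv

    if truth.final_volume <= truth.rv_post:
        raise SimulationError("final volume does not exceed the residual volume")
    drain_volume = truth.final_volume - truth.rv_post
    alb_final = truth.dialysate_conc["albumin"][-1]
    alb_flush_true = truth.rv_post * alb_final / (config.flush_volume + truth.rv_post)

    # Measurement order is fixed for seed determinism.
    dialysate: dict[str, SoluteSeries] = {}
    for solute in SOLUTES:
        measured = [_noisy(rng, c, cv) for c in truth.dialysate_conc[solute]]
        dialysate[solute] = SoluteSeries(solute, tuple(config.sample_times), tuple(measured))
    plasma: dict[str, PlasmaSeries] = {}
    for solute in _PLASMA_MEASURED:
        level = config.plasma_level.get(solute, 0.0)
        values = tuple(_noisy(rng, level, cv) for _ in PLASMA_TIMES)
        plasma[solute] = PlasmaSeries(solute, PLASMA_TIMES, values)
    alb_overnight = _noisy(rng, config.residual_albumin, cv)
    alb_final_meas = _noisy(rng, alb_final, cv)
    alb_flush_meas = _noisy(rng, alb_flush_true, cv)
    if config.peritonitis:
        leuko = math.exp(rng.normal(math.log(1.0), 0.4))
        diagnostics = EffluentDiagnostics(True, True, leuko, config.duration)
    else:
        leuko = math.exp(rng.normal(math.log(0.02), 0.4))
        diagnostics = EffluentDiagnostics(False, False, leuko, config.duration)

    observables = DwellSamples(
        instilled_volume=config.instilled_volume,
        duration=config.duration,
        drain_volume_end=drain_volume,
        sample_volume_total=truth.sampled_volume,
        albumin_overnight_effluent=alb_overnight,
        albumin_t0=dialysate["albumin"].dialysate_conc[0],
        albumin_final_drain=alb_final_meas,
        albumin_flush=alb_flush_meas,
        flush_volume=config.flush_volume,
        body_weight=config.body_weight,
        dialysate=dialysate,
        plasma=plasma,
        diagnostics=diagnostics,
    )
    return SimulatedDwell(observables=observables, truth=truth, config=config)


def simulate_batch(
    config: SimulationConfig, n: int, seed: int = 0,
    animal_count: int = 5, id_prefix: str = "dwell",
) -> list[SimulatedDwell]:
    """Simulate ``n`` independent dwells with per-dwell seeds derived from ``seed``.

    Dwell identifiers are sequential; animals are assigned round-robin,
    emulating repeated assessments in a small cohort.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    dwells = []
    for i in range(n):
        cfg = config.replace(seed=int(child_seeds[i]))
        dwell = simulate_dwell(cfg)
        dwell.observables.dwell_id = f"{id_prefix}{i + 1:03d}"
        dwell.observables.animal_id = f"pig{(i % animal_count) + 1:02d}"
        dwells.append(dwell)
    return dwells


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------


def scenario_preset(name: str, **overrides) -> SimulationConfig:
    """Named study-condition presets.

    ``low_transporter`` — the slow-transport membrane typical of the
    uninflamed porcine peritoneum: small-solute MTACs at the no-peritonitis
    group means, positive net ultrafiltration (~+200 mL over 4 h).

    ``peritonitis`` — inflamed membrane: urea/creatinine/phosphate MTAC
    roughly doubled, potassium unchanged, glucose absorption faster, and
    lymphatic absorption raised above the (reduced) ultrafiltration so net
    fluid balance is negative (~-160 mL over 4 h).
    """
    if name == "low_transporter":
        config = SimulationConfig()
    elif name == "peritonitis":
        base = SimulationConfig()
        config = base.replace(
            true_mtac={**base.true_mtac, "urea": 12.6, "creatinine": 7.7,
                       "phosphate": 6.0, "potassium": 17.4, "glucose": 6.0},
            uf_rate_initial=1.5,
            lymphatic_rate=1.2,
            peritonitis=True,
        )
    else:
        raise SPAError(f"unknown scenario preset {name!r}")
    if overrides:
        config = config.replace(**overrides)
    return config


# ---------------------------------------------------------------------------
# Longitudinal uremia trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UremiaCourse:
    """Daily plasma concentration trajectory of one solute (mM).

    Starts at the chronic baseline, attains its maximum (``peak``) at
    ``peak_day`` and relaxes exponentially back toward baseline with time
    constant ``recovery_timescale`` (days).
    """

    solute: str
    baseline: float
    peak: float
    peak_day: float
    recovery_timescale: float
    days: np.ndarray
    values: np.ndarray

    def at(self, day: float) -> float:
        return float(np.interp(day, self.days, self.values))


#: Default acute-on-chronic uremia parameters (mM; creatinine 0.212 mM = 212 µM).
UREMIA_DEFAULTS: dict[str, dict[str, float]] = {
    "urea": {"baseline": 3.6, "peak": 16.7},
    "creatinine": {"baseline": 0.212, "peak": 0.932},
}


def simulate_uremia_course(
    solute: str,
    baseline: Optional[float] = None,
    peak: Optional[float] = None,
    peak_day: float = 12.0,
    recovery_timescale: float = 5.5,
    horizon: float = 42.0,
    seed: Optional[int] = None,
    noise_cv: float = 0.0,
) -> UremiaCourse:
    """Generate a daily plasma trajectory for an acute-on-chronic episode.

    The rise uses a smoothstep ramp reaching exactly ``peak`` at
    ``peak_day``; the recovery is exponential toward ``baseline``, slow
    enough that near-baseline is only reached after four weeks with the
    defaults.  Optional multiplicative noise (assay variation) is seeded.
    """
    defaults = UREMIA_DEFAULTS.get(solute, {})
    baseline = defaults.get("baseline") if baseline is None else baseline
    peak = defaults.get("peak") if peak is None else peak
    if baseline is None or peak is None:
        raise SPAError(f"no default trajectory for {solute!r}; give baseline and peak")
    if not (peak > baseline > 0):
        raise SPAError("need peak > baseline > 0")
    if not (0 < peak_day <= horizon):
        raise SPAError("peak_day must lie within the horizon")
    if recovery_timescale <= 0:
        raise SPAError("recovery_timescale must be positive")

    days = np.unique(np.append(np.arange(0.0, math.floor(horizon) + 1.0), peak_day))
    values = np.empty_like(days)
    rise = days <= peak_day
    x = days[rise] / peak_day
    values[rise] = baseline + (peak - baseline) * x * x * (3.0 - 2.0 * x)
    values[~rise] = baseline + (peak - baseline) * np.exp(
        -(days[~rise] - peak_day) / recovery_timescale
    )
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        factors = np.clip(1.0 + noise_cv * rng.standard_normal(days.size), 0.0, None)
        values = values * factors
    return UremiaCourse(
        solute=solute, baseline=float(baseline), peak=float(peak),
        peak_day=float(peak_day), recovery_timescale=float(recovery_timescale),
        days=days, values=values,
    )
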