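"""Unit and property tests for the SPA transport calculations."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spakit.core import (
    DwellSamples,
    GradientCrossoverError,
    IndicatorDilutionError,
    MissingDataError,
    PlasmaSeries,
    SoluteSeries,
    SPAError,
    analyze_batch,
    analyze_spa,
    body_surface_area,
    clearance,
    dd0_ratio,
    dp_ratio,
    mean_plasma,
    mtac_garred,
    net_ultrafiltration,
    residual_volume,
    total_solute_removal,
)

# ---------------------------------------------------------------------------
# residual volume (indicator dilution)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "v_in, c_t0, c_drain, expected",
    [
        (2000.0, 0.0, 2.5, 0.0),  # no marker in the mixture -> no residual fluid
        (2000.0, 0.3, 2.3, 300.0),  # inversion of the analytic mixing relation
    ],
)
def test_residual_volume_examples(v_in, c_t0, c_drain, expected):
    assert residual_volume(v_in, c_t0, c_drain) == pytest.approx(expected, abs=1e-9)


def test_residual_volume_degenerate_marker_raises():
    with pytest.raises(IndicatorDilutionError):
        residual_volume(2000.0, 1.0, 1.0)
    with pytest.raises(IndicatorDilutionError):
        residual_volume(2000.0, 2.0, 1.5)
    with pytest.raises(SPAError):
        residual_volume(0.0, 0.3, 2.3)


@given(
    rv=st.floats(0.0, 800.0),
    c_res=st.floats(0.5, 5.0),
    v_in=st.floats(500.0, 3000.0),
)
def test_residual_volume_inverts_mixing(rv, c_res, v_in):
    """Diluting rv mL of marker fluid into v_in mL and inverting recovers rv."""
    c_t0 = rv * c_res / (v_in + rv)
    est = residual_volume(v_in, c_t0, c_res)
    assert est == pytest.approx(rv, abs=1e-9 + 1e-9 * rv)


# ---------------------------------------------------------------------------
# net ultrafiltration
# ---------------------------------------------------------------------------


def test_net_ultrafiltration_balance():
    assert net_ultrafiltration(2300.0, 0.0, 0.0, 2300.0) == 0.0
    assert net_ultrafiltration(2200.0, 150.0, 40.0, 2300.0) == pytest.approx(90.0)
    # net absorption is a legitimate negative outcome
    assert net_ultrafiltration(2000.0, 100.0, 35.0, 2300.0) < 0
    with pytest.raises(SPAError):
        net_ultrafiltration(-1.0, 0.0, 0.0, 2300.0)


# ---------------------------------------------------------------------------
# Garred MTAC
# ---------------------------------------------------------------------------


def test_mtac_zero_when_nothing_changed():
    assert mtac_garred(2000.0, 2000.0, 240.0, 3.0, 3.0, 5.0) == 0.0


def test_mtac_recovers_closed_form_constant_volume():
    """D(t) = P (1 - exp(-K t / V)) must invert to K exactly."""
    d_t = 10.0 * (1.0 - math.exp(-0.6))
    est = mtac_garred(2000.0, 2000.0, 240.0, 0.0, d_t, 10.0)
    assert est == pytest.approx(5.0, rel=1e-12)


def test_mtac_glucose_negative_gradient():
    """Same closed form run from above plasma (glucose side of the gradient)."""
    k, v, t, p, d0 = 4.0, 2000.0, 240.0, 5.0, 75.0
    d_t = p + (d0 - p) * math.exp(-k * t / v)
    est = mtac_garred(v, v, t, d0, d_t, p)
    assert est == pytest.approx(k, rel=1e-12)


def test_mtac_gradient_crossover_flagged_not_extrapolated():
    with pytest.raises(GradientCrossoverError):
        mtac_garred(2000.0, 2000.0, 240.0, 2.0, 8.0, 5.0)
    with pytest.raises(GradientCrossoverError):
        mtac_garred(2000.0, 2000.0, 240.0, 5.0, 4.0, 5.0)  # zero start gradient


@given(
    k=st.floats(0.5, 30.0),
    v=st.floats(1000.0, 3000.0),
    p=st.floats(1.0, 20.0),
    t=st.floats(60.0, 480.0),
)
def test_mtac_constant_volume_sweep(k, v, p, t):
    """Exactness on the pure-diffusion limit across the physiologic range."""
    d_t = p * (1.0 - math.exp(-k * t / v))
    est = mtac_garred(v, v, t, 0.0, d_t, p)
    assert abs(est - k) / k < 1e-9


@given(
    k=st.floats(0.5, 30.0),
    c=st.floats(-50.0, 50.0),
    p=st.floats(6.0, 20.0),
)
def test_mtac_gradient_reflection_symmetry(k, c, p):
    """Reflecting all concentrations about any constant leaves MTAC unchanged."""
    v, t = 2000.0, 240.0
    d0 = 1.0
    d_t = p + (d0 - p) * math.exp(-k * t / v)
    direct = mtac_garred(v, v, t, d0, d_t, p)
    mirrored = mtac_garred(v, v, t, 2 * c - d0, 2 * c - d_t, 2 * c - p)
    assert mirrored == pytest.approx(direct, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# TSR and clearance
# ---------------------------------------------------------------------------


def test_total_solute_removal():
    assert total_solute_removal(0.0, 2100.0, 0.0, 2000.0) == 0.0
    # 4 mM x 2100 mL = 8.4 mmol removed from zero start
    assert total_solute_removal(4.0, 2100.0, 0.0, 2000.0) == pytest.approx(8.4)
    # glucose is absorbed: negative removal allowed
    assert total_solute_removal(40.0, 2100.0, 75.0, 2000.0) < 0


def test_clearance_unit_conversion():
    assert clearance(0.0, 6.0, 240.0) == 0.0
    # 8400 umol / (6 umol/mL x 240 min) = 5.833 mL/min
    assert clearance(8.4, 6.0, 240.0) == pytest.approx(8400.0 / (6.0 * 240.0))
    with pytest.raises(MissingDataError):
        clearance(8.4, 0.0, 240.0)


# ---------------------------------------------------------------------------
# mean plasma with interpolation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "times, values, expected",
    [
        ((0.0, 120.0, 240.0), (6.0, 6.0, 6.0), 6.0),
        ((0.0, 240.0), (4.0, 8.0), 6.0),  # interior point interpolated
        ((0.0, 120.0, 240.0), (4.0, math.nan, 8.0), 6.0),  # NaN encoding
        ((0.0, 120.0, 240.0), (4.0, 5.0, 9.0), 6.0),
        ((120.0, 240.0), (5.0, 9.0), (5.0 + 5.0 + 9.0) / 3),  # t0 carried
        ((120.0,), (6.0,), 6.0),  # single draw carried both ways
    ],
)
def test_mean_plasma(times, values, expected):
    series = PlasmaSeries("urea", times, values)
    assert mean_plasma(series) == pytest.approx(expected)


def test_all_missing_plasma_rejected():
    with pytest.raises(SPAError):
        PlasmaSeries("urea", (0.0, 120.0), (math.nan, math.nan))


# ---------------------------------------------------------------------------
# ratios and body surface area
# ---------------------------------------------------------------------------


def test_dp_ratio():
    assert dp_ratio(5.0, 5.0) == 1.0
    assert dp_ratio(2.05, 5.0) == pytest.approx(0.41)  # low-transport magnitude
    assert dp_ratio(0.0, 5.0) == 0.0
    with pytest.raises(MissingDataError):
        dp_ratio(2.0, 0.0)


def test_dd0_ratio():
    assert dd0_ratio(75.0, 75.0) == 1.0
    assert dd0_ratio(48.75, 75.0) == pytest.approx(0.65)
    assert dd0_ratio(0.0, 75.0) == 0.0
    with pytest.raises(MissingDataError):
        dd0_ratio(40.0, 0.0)


def test_body_surface_area_power_law():
    a = 0.656
    assert body_surface_area(80.0) == pytest.approx(
        body_surface_area(40.0) * 2.0**a
    )
    assert body_surface_area(1.73, k=1.0, a=1.0) == pytest.approx(1.73)
    assert body_surface_area(100.0) > body_surface_area(40.0)
    with pytest.raises(SPAError):
        body_surface_area(0.0)


# ---------------------------------------------------------------------------
# whole-dwell orchestration and flags
# ---------------------------------------------------------------------------


def _hand_built_dwell(**overrides) -> DwellSamples:
    """A small constant-volume, zero-residual dwell with known parameters."""
    v, t = 2000.0, 240.0
    times = (0.0, 120.0, 240.0)

    def series(solute, k, p, d0=0.0):
        conc = tuple(p + (d0 - p) * math.exp(-k * tt / v) for tt in times)
        return SoluteSeries(solute, times, conc)

    fields = dict(
        instilled_volume=v,
        duration=t,
        drain_volume_end=v,
        sample_volume_total=0.0,
        albumin_overnight_effluent=2.3,
        albumin_t0=0.0,
        albumin_final_drain=2.3,
        albumin_flush=0.0,
        flush_volume=v,
        body_weight=60.0,
        dialysate={
            "urea": series("urea", 8.0, 16.0),
            "creatinine": series("creatinine", 3.3, 1.0),
            "phosphate": series("phosphate", 2.3, 2.6),
            "potassium": series("potassium", 18.0, 4.4),
            "glucose": series("glucose", 4.0, 5.0, d0=75.0),
        },
        plasma={
            s: PlasmaSeries(s, times, (p, p, p))
            for s, p in [("urea", 16.0), ("creatinine", 1.0),
                         ("phosphate", 2.6), ("potassium", 4.4)]
        },
    )
    fields.update(overrides)
    return DwellSamples(**fields)


def test_analyze_spa_recovers_generating_parameters():
    result = analyze_spa(_hand_built_dwell())
    for solute, k in [("urea", 8.0), ("creatinine", 3.3),
                      ("phosphate", 2.3), ("potassium", 18.0)]:
        assert result.solutes[solute].mtac == pytest.approx(k, rel=1e-9)
    assert result.rv_pre == pytest.approx(0.0)
    assert result.rv_post == pytest.approx(0.0)
    assert result.dd0_glucose_4h < 1.0  # glucose disappears into lower plasma


def test_analyze_spa_residual_volume_from_markers():
    """Albumin markers consistent with a 300 mL residual invert to 300 mL."""
    dwell = _hand_built_dwell(
        albumin_t0=300.0 * 2.3 / 2300.0, albumin_flush=300.0 * 2.3 / 2300.0
    )
    result = analyze_spa(dwell)
    assert result.rv_pre == pytest.approx(300.0)
    assert result.rv_post == pytest.approx(300.0)


def test_analyze_spa_normalization_consistency():
    result = analyze_spa(_hand_built_dwell())
    assert result.bsa is not None
    for rec in result.solutes.values():
        if rec.mtac is not None:
            assert rec.mtac_normalized == pytest.approx(rec.mtac * 1.73 / result.bsa)
        if rec.clearance is not None:
            assert rec.clearance_normalized == pytest.approx(
                rec.clearance * 1.73 / result.bsa
            )
        # diffusion-only transport: clearance cannot exceed the maximal clearance
        if rec.mtac is not None and rec.clearance is not None:
            assert rec.clearance < rec.mtac


def test_analyze_spa_marker_failure_flags_but_keeps_ratios():
    dwell = _hand_built_dwell(albumin_overnight_effluent=0.2, albumin_t0=0.3)
    result = analyze_spa(dwell)
    assert result.rv_pre is None
    assert "rv_pre" in result.flags
    assert result.ufv_net is None
    assert "ufv_net" in result.flags
    # ratios and MTAC do not need the residual volume
    assert result.dp_urea_4h is not None
    assert result.dp_creatinine_4h is not None
    assert result.dd0_glucose_4h is not None
    assert result.solutes["urea"].mtac is not None
    # but TSR/clearance do
    assert result.solutes["urea"].tsr is None


def test_analyze_spa_missing_plasma_flagged_not_dropped():
    dwell = _hand_built_dwell()
    del dwell.plasma["creatinine"]
    result = analyze_spa(dwell)
    assert result.solutes["creatinine"].mtac is None
    assert any("plasma" in note for note in result.flags["creatinine"])
    assert result.solutes["urea"].mtac is not None


def test_analyze_batch_preserves_order():
    dwells = [_hand_built_dwell() for _ in range(3)]
    for i, d in enumerate(dwells):
        d.dwell_id = f"d{i}"
    results = analyze_batch(dwells)
    assert [r.dwell_id for r in results] == ["d0", "d1", "d2"]


def test_dp_denominator_policy():
    dwell = _hand_built_dwell()
    # constant plasma: both policies agree
    r1 = analyze_spa(dwell, dp_denominator="t240")
    r2 = analyze_spa(dwell, dp_denominator="mean")
    assert r1.dp_urea_4h == pytest.approx(r2.dp_urea_4h)
    with pytest.raises(SPAError):
        analyze_spa(dwell, dp_denominator="plasma_at_dawn")
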