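"""End-to-end analysis: traces -> calibrated force partition -> stiffness
series -> trend statistics, plus CT morphometry with contralateral
normalization, and cohort-level aggregation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import ct as ct_mod
from .gait import (
    DEFAULT_HEALTHY_FRACTION,
    ForceTrace,
    daily_summary,
    detect_stance_phases,
    peak_per_tread,
)
from .mechanics import (
    DEFAULT_CALIBRATION_WINDOW,
    DEFAULT_CENSOR_FRACTION,
    CalibrationRatio,
    StiffnessSet,
    estimate_callus_stiffness,
)
from .trends import (
    DEFAULT_STABILITY_BAND_FRACTION,
    DEFAULT_STABILITY_HOLD_DAYS,
    detect_crossover_day,
    detect_stabilization,
    grf_bmd_regression,
)

logger = logging.getLogger(__name__)

DAILY_COLUMNS = [
    "day", "n_treads", "grf_N", "ff_N", "grf_pct", "complete",
    "f_i_N", "f_c_N", "k_c_N_mm", "censored", "status",
]


@dataclass
class AnimalAnalysis:
    """Per-animal mechanical monitoring result."""

    animal_id: str
    ratio: CalibrationRatio
    daily: pd.DataFrame  # one row per monitoring day (DAILY_COLUMNS)
    crossover_day: Optional[float]
    stabilization_day: Optional[float]
    stiffness: StiffnessSet

    def k_c_at(self, day: float) -> float:
        """Numeric K_c estimate (N/mm) on an exact monitoring day."""
        row = self.daily[self.daily["day"] == day]
        if row.empty:
            raise KeyError(f"no monitoring data on day {day}")
        return float(row["k_c_N_mm"].iloc[0])


def analyze_gait_traces(
    traces: Sequence[ForceTrace],
    stiffness: StiffnessSet,
    body_weight_kg: float,
    healthy_fraction: float = DEFAULT_HEALTHY_FRACTION,
    calibration_window: tuple[float, float] = DEFAULT_CALIBRATION_WINDOW,
    censor_fraction: float = DEFAULT_CENSOR_FRACTION,
    stability_band_fraction: float = DEFAULT_STABILITY_BAND_FRACTION,
    stability_hold_days: float = DEFAULT_STABILITY_HOLD_DAYS,
) -> AnimalAnalysis:
    """Run the full mechanical monitoring pipeline for one animal.

    Detects stances and per-tread peaks, calibrates the internal-force
    ratio on the early window, builds the daily force-partition series
    (F_i, F_f, F_c), estimates the apparent callus stiffness with
    measurement-range censoring, and locates the load-share crossover and
    the fixator-force stabilization day.
    """
    from .mechanics import calibrate_force_ratio  # local to avoid cycle noise

    per_day_peaks = []
    all_peaks = []
    for trace in sorted(traces, key=lambda tr: tr.day):
        stances = detect_stance_phases(trace, body_weight_kg)
        peaks = peak_per_tread(trace, stances)
        if not peaks:
            logger.warning("no stances detected on day %.1f", trace.day)
            continue
        per_day_peaks.append(peaks)
        all_peaks.extend(peaks)

    ratio = calibrate_force_ratio(all_peaks, calibration_window)

    rows = []
    for peaks in per_day_peaks:
        summ = daily_summary(peaks, body_weight_kg, healthy_fraction)
        f_i = ratio.r * summ.mean_grf
        f_c = f_i - summ.mean_ff
        k_c, status = estimate_callus_stiffness(
            f_i, summ.mean_ff, stiffness.k_f, stiffness.k_b, censor_fraction
        )
        rows.append(
            {
                "day": summ.day,
                "n_treads": summ.n_treads,
                "grf_N": summ.mean_grf,
                "ff_N": summ.mean_ff,
                "grf_pct": summ.grf_pct_healthy,
                "complete": summ.complete,
                "f_i_N": f_i,
                "f_c_N": f_c,
                "k_c_N_mm": np.nan if k_c is None else k_c,
                "censored": status == "censored",
                "status": status,
            }
        )
    daily = pd.DataFrame(rows, columns=DAILY_COLUMNS)

    crossover = detect_crossover_day(daily["day"], daily["ff_N"], daily["f_c_N"])
    band = stability_band_fraction * float(daily["f_i_N"].mean())
    stabilization = detect_stabilization(
        daily["day"], daily["ff_N"], band, stability_hold_days
    )
    animal_id = traces[0].animal_id if traces else ""
    return AnimalAnalysis(
        animal_id=animal_id,
        ratio=ratio,
        daily=daily,
        crossover_day=crossover,
        stabilization_day=stabilization,
        stiffness=stiffness,
    )


def analyze_ct_volume(
    volume: ct_mod.VoxelVolume,
    control: Optional[ct_mod.VoxelVolume] = None,
    density_threshold: float = ct_mod.DEFAULT_DENSITY_THRESHOLD,
    margin_mm: float = ct_mod.DEFAULT_TV_MARGIN,
) -> dict:
    """Morphometry of one volume, optionally normalized to a control limb."""
    profile = ct_mod.morphometry(volume, density_threshold=density_threshold, margin_mm=margin_mm)
    out = {
        "tv_cm3": profile.tv_cm3,
        "csa_mm2": profile.csa_mean_mm2,
        "bmd_g_cm3": profile.bmd_mean_g_cm3,
        "profile": profile,
    }
    if control is not None:
        control_profile = ct_mod.morphometry(
            control, density_threshold=density_threshold, margin_mm=margin_mm
        )
        out["percent_of_control"] = ct_mod.normalize_to_contralateral(profile, control_profile)
        out["control_profile"] = control_profile
    return out


def cohort_summary(
    analyses: Sequence[AnimalAnalysis],
    ct_results: Optional[dict[str, list[dict]]] = None,
) -> dict:
    """Aggregate per-animal analyses into cohort-level statistics.

    Returns mean crossover/stabilization days, the calibrated ratios and,
    when CT results with matched gait days are supplied, the GRF-BMD
    regression over (%BW-normalized GRF, BMD) pairs.
    """
    crossovers = [a.crossover_day for a in analyses if a.crossover_day is not None]
    stabilizations = [a.stabilization_day for a in analyses if a.stabilization_day is not None]
    out = {
        "n_animals": len(analyses),
        "mean_crossover_day": float(np.mean(crossovers)) if crossovers else None,
        "mean_stabilization_day": float(np.mean(stabilizations)) if stabilizations else None,
        "calibration_ratios": {a.animal_id: a.ratio.r for a in analyses},
    }
    if ct_results:
        pairs = _grf_bmd_pairs(analyses, ct_results)
        if len(pairs) >= 3:
            grf_vals, bmd_vals = zip(*pairs)
            try:
                reg = grf_bmd_regression(grf_vals, bmd_vals)
                out["grf_bmd_regression"] = {
                    "slope": reg.slope,
                    "intercept": reg.intercept,
                    "r_squared": reg.r_squared,
                    "p_value": reg.p_value,
                    "n": reg.n,
                    "significant": reg.significant,
                }
            except ValueError as exc:
                logger.warning("GRF-BMD regression skipped: %s", exc)
    return out


def _grf_bmd_pairs(
    analyses: Sequence[AnimalAnalysis], ct_results: dict[str, list[dict]]
) -> list[tuple[float, float]]:
    """Pair each CT time-point's BMD with the nearest-day %BW GRF (<=7 d)."""
    pairs = []
    by_id = {a.animal_id: a for a in analyses}
    for animal_id, entries in ct_results.items():
        analysis = by_id.get(animal_id)
        if analysis is None or analysis.daily.empty:
            continue
        days = analysis.daily["day"].to_numpy()
        # %BW uses the raw body-weight normalization, not the healthy fraction
        grf_pct_bw = (
            analysis.daily["grf_pct"].to_numpy() * DEFAULT_HEALTHY_FRACTION
        )
        for entry in entries:
            bmd = entry.get("bmd_g_cm3")
            day = entry.get("day")
            if bmd is None or day is None or not np.isfinite(bmd):
                continue
            i = int(np.argmin(np.abs(days - day)))
            if abs(days[i] - day) <= 7.0:
                pairs.append((float(grf_pct_bw[i]), float(bmd)))
    return pairs
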