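"""Gait ground-reaction-force processing.

Raw walking-platform traces (vertical GRF) recorded simultaneously with the
fixator load cells are segmented into stance phases, reduced to per-tread
peak forces, and summarized per day.  Daily mean peak GRF is normalized to
the healthy reference for this animal model: a sound limb exerts 42-43 % of
body weight at an amble, so the default healthy fraction is 0.425.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mechanics import LoadState

logger = logging.getLogger(__name__)

GRAVITY = 9.81  # m/s^2
DEFAULT_HEALTHY_FRACTION = 0.425  # peak GRF of a sound limb as fraction of BW
DEFAULT_STANCE_THRESHOLD_BW = 0.05
DEFAULT_HYSTERESIS_BW = 0.01
DEFAULT_MIN_STANCE_DURATION = 0.2  # s
MIN_TREADS_COMPLETE = 8

TRACE_COLUMNS = ["day", "tread_id", "t", "grf_N", "ff_N"]


@dataclass
class ForceTrace:
    """One day's synchronized platform/fixator recording for one animal.

    ``t`` must be uniformly sampled; ``grf`` is assumed baseline-corrected
    (zero off-stance).  ``tread_id`` is optional bookkeeping: the generating
    tread index per sample (-1 off-stance), carried through file I/O.
    """

    t: np.ndarray
    grf: np.ndarray
    ff: np.ndarray
    day: float
    animal_id: str = ""
    tread_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.grf = np.asarray(self.grf, dtype=float)
        self.ff = np.asarray(self.ff, dtype=float)
        if not (self.t.shape == self.grf.shape == self.ff.shape):
            raise ValueError("t, grf and ff must have identical shapes")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("trace must be uniformly sampled")

    @property
    def sample_rate(self) -> float:
        if self.t.size < 2:
            raise ValueError("need >= 2 samples to define a sample rate")
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class DailyGaitSummary:
    """Daily means over treads, with GRF expressed as % of healthy."""

    day: float
    n_treads: int
    mean_grf: float
    mean_ff: float
    grf_pct_healthy: float
    complete: bool


def healthy_grf(body_weight_kg: float, healthy_fraction: float = DEFAULT_HEALTHY_FRACTION) -> float:
    """Healthy-limb peak GRF reference (N) for a given body weight."""
    return healthy_fraction * body_weight_kg * GRAVITY


def detect_stance_phases(
    trace: ForceTrace,
    body_weight_kg: float,
    threshold_bw: float = DEFAULT_STANCE_THRESHOLD_BW,
    hysteresis_bw: float = DEFAULT_HYSTERESIS_BW,
    min_duration_s: float = DEFAULT_MIN_STANCE_DURATION,
) -> list[tuple[int, int]]:
    """Find stance phases as half-open sample intervals ``[i0, i1)``.

    A stance starts when GRF rises to ``threshold_bw`` of body weight and
    ends when it falls below the threshold minus a ``hysteresis_bw`` band
    (chatter guard).  Intervals shorter than ``min_duration_s`` are
    discarded; a stance clipped at the trace end is kept if it already
    meets the duration criterion.  Intervals are disjoint and ordered.
    """
    if trace.t.size == 0:
        return []
    bw_force = body_weight_kg * GRAVITY
    hi = threshold_bw * bw_force
    lo = hi - hysteresis_bw * bw_force
    dt = 1.0 / trace.sample_rate if trace.t.size >= 2 else 0.0
    min_samples = int(np.ceil(min_duration_s / dt)) if dt > 0 else 1

    intervals: list[tuple[int, int]] = []
    in_stance = False
    start = 0
    for i, g in enumerate(trace.grf):
        if not in_stance and g >= hi:
            in_stance = True
            start = i
        elif in_stance and g < lo:
            if i - start >= min_samples:
                intervals.append((start, i))
            in_stance = False
    if in_stance and trace.grf.size - start >= min_samples:
        intervals.append((start, trace.grf.size))
    return intervals


def peak_per_tread(trace: ForceTrace, stances: Sequence[tuple[int, int]]) -> list[LoadState]:
    """Reduce each stance to its peak forces.

    GRF and fixator-force peaks are taken as the maxima over the same
    stance interval (peak-synchronized pairing); the internal force is
    filled in later once the calibration ratio is known.
    """
    peaks = []
    for i0, i1 in stances:
        peaks.append(
            LoadState(
                day=trace.day,
                grf=float(np.max(trace.grf[i0:i1])),
                f_f=float(np.max(trace.ff[i0:i1])),
            )
        )
    return peaks


def daily_summary(
    peaks: Sequence[LoadState],
    body_weight_kg: float,
    healthy_fraction: float = DEFAULT_HEALTHY_FRACTION,
    min_treads: int = MIN_TREADS_COMPLETE,
) -> DailyGaitSummary:
    """Average per-tread peaks into a daily summary.

    ``grf_pct_healthy = 100 * mean_peak / (healthy_fraction * BW * g)``.
    A day is ``complete`` when it has at least ``min_treads`` treads
    (incomplete days are kept, flagged, not dropped).
    """
    if not peaks:
        raise ValueError("daily summary requires at least one tread")
    days = {p.day for p in peaks}
    if len(days) != 1:
        raise ValueError(f"peaks span multiple days: {sorted(days)}")
    mean_grf = float(np.mean([p.grf for p in peaks]))
    mean_ff = float(np.mean([p.f_f for p in peaks]))
    ref = healthy_grf(body_weight_kg, healthy_fraction)
    return DailyGaitSummary(
        day=float(peaks[0].day),
        n_treads=len(peaks),
        mean_grf=mean_grf,
        mean_ff=mean_ff,
        grf_pct_healthy=100.0 * mean_grf / ref,
        complete=len(peaks) >= min_treads,
    )


def write_trace_csv(traces: Sequence[ForceTrace], path: str | Path) -> None:
    """Write traces in the tabular dialect: day, tread_id, t, grf_N, ff_N."""
    frames = []
    for tr in traces:
        tread = tr.tread_id if tr.tread_id is not None else np.full(tr.t.shape, -1, dtype=int)
        frames.append(
            pd.DataFrame(
                {
                    "day": tr.day,
                    "tread_id": np.asarray(tread, dtype=int),
                    "t": tr.t,
                    "grf_N": tr.grf,
                    "ff_N": tr.ff,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace_csv(path: str | Path, animal_id: str = "") -> list[ForceTrace]:
    """Read a trace CSV back into one :class:`ForceTrace` per day."""
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV {path} missing columns: {sorted(missing)}")
    traces = []
    for day, group in df.groupby("day", sort=True):
        traces.append(
            ForceTrace(
                t=group["t"].to_numpy(),
                grf=group["grf_N"].to_numpy(),
                ff=group["ff_N"].to_numpy(),
                day=float(day),
                animal_id=animal_id,
                tread_id=group["tread_id"].to_numpy(),
            )
        )
    return traces
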