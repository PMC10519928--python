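"""Forward simulation of a healing cohort with known ground truth.

Generates the data the analysis pipeline consumes — gait/fixator force
traces and CT-like volumes with calibration phantoms — from per-animal
ground-truth trajectories, so every pipeline stage can be scored against
a known answer:

- an apparent callus-stiffness trajectory K_c(t) through anchor points
  (60 N/mm at day 14, the half-share stiffness K_f*K_b/(K_b+K_f) at day
  30, 650 N/mm at day 40, 7 kN/mm at day 60, 15 kN/mm at day 70), held
  at exactly zero before bridging onset (first anchor day) so the
  early-window F_i ~= F_f assumption holds exactly in the simulator;
- a GRF recovery curve (42 % of healthy the week after latency, ~70 % at
  four months, 93 % at half a year);
- a callus mineral-density trajectory (0.45 g HA/cm^3 at implantation —
  36 % of the 1.25 g HA/cm^3 contralateral cortical value — through 0.79
  at day 65, 0.81 at day 123, 95 % of control at one year);
- a cross-sectional overgrowth trajectory (100 % of the 144.79 mm^2
  contralateral CSA at implantation, peaking at ~229 % near day 200).

Trajectories use monotone shape-preserving (PCHIP) interpolation through
the anchors — the printed anchors are inconsistent with any single
exponential — and hold their end values outside the anchor range.
Fragment stiffnesses default to the per-animal estimates of the study
cohort (K_b recomputed from the series formula).  Stance pulses are
half-sines: the pipeline only consumes peaks, so any pulse with a unique
maximum would do.  Sensor noise is multiplicative Gaussian on per-tread
peaks (default 5 %); CT noise is additive Gaussian HU (default 2 HU) plus
voxel-level density texture in the callus (default 0.05 g HA/cm^3).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from . import ct
from .gait import ForceTrace, healthy_grf
from .mechanics import (
    DEFAULT_FIXATOR_STIFFNESS,
    StiffnessSet,
    forward_load_partition,
    series_equivalent_stiffness,
)

logger = logging.getLogger(__name__)

#: Per-animal fragment stiffness fixtures (kN/mm) with sacrifice day and
#: CT time-points: (id, K_bp, K_bd, sacrifice_day, ct_days).
COHORT_FIXTURES: list[tuple[str, float, float, int, tuple[int, ...]]] = [
    ("S1", 309.85, 356.74, 365, (176, 285, 365)),
    ("S2", 144.51, 138.36, 219, (219,)),
    ("S3", 199.86, 206.13, 194, (158, 194)),
    ("S4", 173.25, 190.27, 152, (152,)),
    ("S5", 236.96, 333.16, 123, (123,)),
    ("S6", 160.67, 136.69, 65, (65,)),
    ("S7", 206.71, 219.49, 51, (51,)),
    ("S8", 218.43, 236.98, 30, (30,)),
]

#: Printed series-equivalent stiffness (kN/mm) for the rows the series
#: formula reproduces to +-0.01 (S5 is excluded: probable typo).
PRINTED_EQUIVALENT_STIFFNESS_KN = {
    "S1": 165.82, "S2": 70.68, "S3": 101.47, "S4": 90.68,
    "S6": 73.86, "S7": 106.45, "S8": 113.67,
}

# Contralateral (healthy-limb) references over a 15 mm span.
CONTROL_TV_CM3 = 2.17
CONTROL_CSA_MM2 = 144.79
CONTROL_BMD_G_CM3 = 1.25

DEFAULT_GRF_ANCHORS = ((7.0, 42.0), (120.0, 70.5), (180.0, 93.0))  # (day, % healthy)
DEFAULT_BMD_ANCHORS = ((0.0, 0.45), (65.0, 0.79), (123.0, 0.81), (365.0, 1.1875))
DEFAULT_CSA_PCT_ANCHORS = ((0.0, 100.0), (200.0, 229.49), (365.0, 156.13))

DEFAULT_SENSOR_SIGMA = 0.05  # multiplicative, per-tread sensor peaks
DEFAULT_HU_SIGMA = 2.0  # additive HU
DEFAULT_BMD_VOXEL_SIGMA = 0.05  # g HA/cm^3, callus texture

# True HU <-> density line used to synthesize volumes; the pipeline must
# recover it from the phantom inserts, never read it.
TRUE_CAL_SLOPE = 0.00075  # g HA/cm^3 per HU
TRUE_CAL_INTERCEPT = -0.03  # g HA/cm^3

DEFAULT_GAIT_DAYS = tuple(range(7, 91))
STANCE_DURATION_S = 0.5
STANCE_GAP_S = 0.4

# Digital-metatarsus geometry (mm).
CORTICAL_OUTER_RADIUS = 9.0
DEFECT_SPAN = (15.0, 30.0)  # 15 mm defect, half-open, within a 45 mm scan
VOLUME_EXTENT_X = (-22.5, 22.5)
VOLUME_EXTENT_Y = (-27.0, 15.0)
VOLUME_EXTENT_Z = (0.0, 45.0)
PHANTOM_RADIUS = 2.5
PHANTOM_ROW_Y = -19.5
PHANTOM_CENTERS_X = (-17.5, -10.5, -3.5, 3.5, 10.5, 17.5)
ROI_BOX = {"x_mm": (-12.5, 12.5), "y_mm": (-12.5, 12.5)}


def trajectory(anchors: Sequence[tuple[float, float]], t: np.ndarray | float) -> np.ndarray | float:
    """Monotone shape-preserving interpolation through anchor points.

    Passes through every anchor exactly, never overshoots between
    monotone anchors (PCHIP), and holds the end values outside the anchor
    range.  Requires >= 2 anchors with strictly increasing days.
    """
    pts = sorted(anchors)
    if len(pts) < 2:
        raise ValueError("trajectory needs >= 2 anchors")
    days = np.array([p[0] for p in pts], dtype=float)
    vals = np.array([p[1] for p in pts], dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError(f"duplicate anchor days in {days.tolist()}")
    interp = PchipInterpolator(days, vals, extrapolate=False)
    tt = np.asarray(t, dtype=float)
    out = np.asarray(interp(np.clip(tt, days[0], days[-1])))
    out = np.where(tt <= days[0], vals[0], np.where(tt >= days[-1], vals[-1], out))
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


@dataclass
class AnimalGroundTruth:
    """Everything needed to synthesize (and later score) one animal."""

    animal_id: str
    k_bp: float  # N/mm
    k_bd: float  # N/mm
    body_weight: float = 60.0  # kg
    k_f: float = DEFAULT_FIXATOR_STIFFNESS
    r_true: float = 1.0  # internal force / GRF
    k_c_anchors: tuple[tuple[float, float], ...] = ()
    grf_anchors: tuple[tuple[float, float], ...] = DEFAULT_GRF_ANCHORS
    bmd_anchors: tuple[tuple[float, float], ...] = DEFAULT_BMD_ANCHORS
    csa_pct_anchors: tuple[tuple[float, float], ...] = DEFAULT_CSA_PCT_ANCHORS
    sensor_sigma: float = DEFAULT_SENSOR_SIGMA
    hu_sigma: float = DEFAULT_HU_SIGMA
    bmd_voxel_sigma: float = DEFAULT_BMD_VOXEL_SIGMA
    sacrifice_day: int = 365
    ct_days: tuple[int, ...] = (365,)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.k_c_anchors:
            self.k_c_anchors = default_stiffness_anchors(self.k_f, self.k_b)
        for name in ("sensor_sigma", "hu_sigma", "bmd_voxel_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for anchors in (self.k_c_anchors, self.grf_anchors, self.bmd_anchors, self.csa_pct_anchors):
            days = [a[0] for a in anchors]
            if sorted(days) != days or len(set(days)) != len(days):
                raise ValueError(f"anchor days must be strictly increasing: {days}")
        if any(v >= self.k_b for _, v in self.k_c_anchors):
            raise ValueError("callus-stiffness anchors must stay below k_b")

    @property
    def k_b(self) -> float:
        return series_equivalent_stiffness(self.k_bp, self.k_bd)

    @property
    def stiffness(self) -> StiffnessSet:
        return StiffnessSet(k_bp=self.k_bp, k_bd=self.k_bd, k_f=self.k_f)

    @property
    def bridging_day(self) -> float:
        """Day bridging begins; K_c is exactly zero before it."""
        return self.k_c_anchors[0][0]

    def callus_stiffness(self, day: float) -> float:
        if day < self.bridging_day:
            return 0.0
        return float(trajectory(self.k_c_anchors, day))

    def grf_pct(self, day: float) -> float:
        return float(trajectory(self.grf_anchors, day))

    def bmd(self, day: float) -> float:
        return float(trajectory(self.bmd_anchors, day))

    def csa_pct(self, day: float) -> float:
        return float(trajectory(self.csa_pct_anchors, day))


def default_stiffness_anchors(k_f: float, k_b: float) -> tuple[tuple[float, float], ...]:
    """Default K_c anchor schedule: bridging at day 14, half-share at day
    30 (force-partition crossover), 650 N/mm at day 40, 7 kN/mm at day 60
    and 15 kN/mm at day 70."""
    k_half = k_f * k_b / (k_b + k_f)
    return ((14.0, 60.0), (30.0, k_half), (40.0, 650.0), (60.0, 7000.0), (70.0, 15000.0))


def default_cohort(
    n: int = 8,
    seed: int = 0,
    jitter: float = 0.0,
    body_weight: float = 60.0,
    sensor_sigma: float = DEFAULT_SENSOR_SIGMA,
    hu_sigma: float = DEFAULT_HU_SIGMA,
) -> list[AnimalGroundTruth]:
    """Build ``n`` ground-truth animals from the per-animal stiffness fixtures.

    Fragment stiffnesses cycle through the cohort fixtures; with
    ``jitter`` > 0 every anchor *value* is scaled per animal by a
    multiplicative Gaussian factor (days are fixed).  Identical seeds give
    bit-identical cohorts.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    children = np.random.SeedSequence(seed).spawn(n)
    animals = []
    for i in range(n):
        sid, k_bp_kn, k_bd_kn, sac_day, ct_days = COHORT_FIXTURES[i % len(COHORT_FIXTURES)]
        animal_seed = int(children[i].generate_state(1)[0] % (2**31))
        truth = AnimalGroundTruth(
            animal_id=f"A{i + 1:02d}_{sid}",
            k_bp=k_bp_kn * 1000.0,
            k_bd=k_bd_kn * 1000.0,
            body_weight=body_weight,
            sensor_sigma=sensor_sigma,
            hu_sigma=hu_sigma,
            sacrifice_day=sac_day,
            ct_days=ct_days,
            seed=animal_seed,
        )
        if jitter > 0:
            rng = np.random.default_rng(animal_seed)

            def _jit(anchors):
                return tuple(
                    (d, v * max(1.0 + jitter * rng.standard_normal(), 0.05))
                    for d, v in anchors
                )

            truth = dataclasses.replace(
                truth,
                k_c_anchors=_jit(truth.k_c_anchors),
                grf_anchors=_jit(truth.grf_anchors),
                bmd_anchors=_jit(truth.bmd_anchors),
                csa_pct_anchors=_jit(truth.csa_pct_anchors),
            )
        animals.append(truth)
    return animals


# ---------------------------------------------------------------------------
# Gait traces
# ---------------------------------------------------------------------------

def simulate_gait_day(
    truth: AnimalGroundTruth,
    day: float,
    n_treads: int = 8,
    sample_rate: float = 100.0,
    noise_sigma: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> ForceTrace:
    """Synthesize one day's platform + fixator recording.

    Each tread is a half-sine stance pulse whose designed peak GRF follows
    the recovery trajectory; the fixator channel carries the share given by
    the forward load partition at the day's true callus stiffness.
    Independent multiplicative noise is applied per tread to each sensor's
    peak.  Stance onsets sit on the sample grid so the designed peak value
    is attained exactly when noise is zero.
    """
    if day < 0:
        raise ValueError(f"day must be >= 0, got {day}")
    if n_treads < 1:
        raise ValueError(f"n_treads must be >= 1, got {n_treads}")
    sigma = truth.sensor_sigma if noise_sigma is None else noise_sigma
    if rng is None:
        rng = np.random.default_rng([truth.seed, int(round(day * 1000))])

    peak_grf = truth.grf_pct(day) / 100.0 * healthy_grf(truth.body_weight)
    f_i = truth.r_true * peak_grf
    k_c = truth.callus_stiffness(day)
    f_f, _ = forward_load_partition(f_i, k_c, truth.k_f, truth.k_b)

    dt = 1.0 / sample_rate
    lead = 0.2
    period = STANCE_DURATION_S + STANCE_GAP_S
    n_samples = int(round((lead + n_treads * period + lead) / dt))
    t = np.arange(n_samples) * dt
    grf = np.zeros(n_samples)
    ff = np.zeros(n_samples)
    tread_id = np.full(n_samples, -1, dtype=int)

    for j in range(n_treads):
        t0 = lead + j * period
        in_stance = (t >= t0) & (t <= t0 + STANCE_DURATION_S)
        hump = np.sin(np.pi * (t[in_stance] - t0) / STANCE_DURATION_S)
        g_factor = max(1.0 + sigma * rng.standard_normal(), 0.05)
        f_factor = max(1.0 + sigma * rng.standard_normal(), 0.05)
        grf[in_stance] = peak_grf * g_factor * hump
        ff[in_stance] = f_f * f_factor * hump
        tread_id[in_stance] = j

    return ForceTrace(t=t, grf=grf, ff=ff, day=float(day),
                      animal_id=truth.animal_id, tread_id=tread_id)


def simulate_gait_series(
    truth: AnimalGroundTruth,
    days: Sequence[float] = DEFAULT_GAIT_DAYS,
    n_treads: int = 8,
    noise_sigma: Optional[float] = None,
) -> list[ForceTrace]:
    """One trace per monitoring day (daily by default, days 7-90)."""
    return [
        simulate_gait_day(truth, d, n_treads=n_treads, noise_sigma=noise_sigma)
        for d in days
    ]


# ---------------------------------------------------------------------------
# CT volumes
# ---------------------------------------------------------------------------

def _grid(spacing: float) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    nx = int(round((VOLUME_EXTENT_X[1] - VOLUME_EXTENT_X[0]) / spacing))
    ny = int(round((VOLUME_EXTENT_Y[1] - VOLUME_EXTENT_Y[0]) / spacing))
    nz = int(round((VOLUME_EXTENT_Z[1] - VOLUME_EXTENT_Z[0]) / spacing))
    origin = (VOLUME_EXTENT_X[0], VOLUME_EXTENT_Y[0], VOLUME_EXTENT_Z[0])
    return (nx, ny, nz), origin


def simulate_ct_volume(
    truth: AnimalGroundTruth,
    day: float,
    spacing: float = 0.3,
    limb: str = "treated",
    hu_sigma: Optional[float] = None,
    bmd_voxel_sigma: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> ct.VoxelVolume:
    """Synthesize a phantom-bearing CT-like volume of one limb.

    The digital metatarsus is a cortical annulus (1.25 g HA/cm^3) along
    the scan; in the treated limb the 15 mm defect span holds a solid
    callus cylinder whose radius follows the CSA% trajectory and whose
    voxel densities are Gaussian around the day's BMD.  Six phantom rods
    of known density sit below the limb.  Densities map to HU through the
    generator's true line plus additive HU noise.  ``volume.meta["truth"]``
    records designed and voxelized ground truth for scoring.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    if limb not in ("treated", "control"):
        raise ValueError(f"limb must be 'treated' or 'control', got {limb!r}")
    h_sigma = truth.hu_sigma if hu_sigma is None else hu_sigma
    v_sigma = truth.bmd_voxel_sigma if bmd_voxel_sigma is None else bmd_voxel_sigma
    if rng is None:
        rng = np.random.default_rng([truth.seed, 7_000_000 + int(round(day * 100)),
                                     0 if limb == "treated" else 1])

    shape, origin = _grid(spacing)
    sp = (spacing, spacing, spacing)
    nx, ny, nz = shape
    x = origin[0] + (np.arange(nx) + 0.5) * spacing
    y = origin[1] + (np.arange(ny) + 0.5) * spacing
    z = origin[2] + (np.arange(nz) + 0.5) * spacing
    r2 = x[:, None] ** 2 + y[None, :] ** 2  # about the bone axis

    inner_radius = float(np.sqrt(CORTICAL_OUTER_RADIUS**2 - CONTROL_CSA_MM2 / np.pi))
    annulus = (r2 <= CORTICAL_OUTER_RADIUS**2) & (r2 > inner_radius**2)
    in_defect_z = (z >= DEFECT_SPAN[0]) & (z < DEFECT_SPAN[1])

    density = np.zeros(shape)
    cortical_z = ~in_defect_z if limb == "treated" else np.ones(nz, dtype=bool)
    density[annulus[:, :, None] & cortical_z[None, None, :]] = CONTROL_BMD_G_CM3

    callus_mean = float("nan")
    callus_radius = float("nan")
    if limb == "treated":
        callus_mean = truth.bmd(day)
        callus_area = truth.csa_pct(day) / 100.0 * CONTROL_CSA_MM2
        callus_radius = float(np.sqrt(callus_area / np.pi))
        callus = (r2 <= callus_radius**2)[:, :, None] & in_defect_z[None, None, :]
        n_callus = int(callus.sum())
        density[callus] = callus_mean + v_sigma * rng.standard_normal(n_callus)

    phantom_meta = []
    for cx, rho in zip(PHANTOM_CENTERS_X, ct.DEFAULT_PHANTOM_DENSITIES):
        mask = (x[:, None] - cx) ** 2 + (y[None, :] - PHANTOM_ROW_Y) ** 2 <= PHANTOM_RADIUS**2
        density[mask[:, :, None] & np.ones(nz, dtype=bool)[None, None, :]] = rho
        phantom_meta.append(
            {"label": f"rho{rho:.1f}", "density_g_cm3": rho,
             "center_xy_mm": [cx, PHANTOM_ROW_Y], "radius_mm": PHANTOM_RADIUS}
        )

    hu = (density - TRUE_CAL_INTERCEPT) / TRUE_CAL_SLOPE
    if h_sigma > 0:
        hu = hu + h_sigma * rng.standard_normal(shape)

    phantoms = [
        ct.PhantomInsert(
            label=p["label"], density=p["density_g_cm3"],
            mask=ct.cylinder_mask(shape, sp, origin, p["center_xy_mm"], p["radius_mm"]),
        )
        for p in phantom_meta
    ]
    roi = ct.box_mask(shape, sp, origin, ROI_BOX["x_mm"], ROI_BOX["y_mm"])

    # Voxelized ground truth from the generator's own mineralized geometry.
    mineral = density >= ct.DEFAULT_DENSITY_THRESHOLD
    for p in phantoms:
        mineral &= ~p.mask
    mineral &= roi
    voxel_csa = mineral.sum(axis=(0, 1)).astype(float) * spacing * spacing
    tv_lo = DEFECT_SPAN[0] - ct.DEFAULT_TV_MARGIN
    tv_hi = DEFECT_SPAN[1] + ct.DEFAULT_TV_MARGIN
    tv_sel = (z >= tv_lo) & (z < tv_hi)
    voxel_tv = float(voxel_csa[tv_sel].sum() * spacing / 1000.0)
    span_mineral = mineral & in_defect_z[None, None, :]
    realized_bmd = float(density[span_mineral].mean()) if span_mineral.any() else float("nan")

    truth_meta = {
        "limb": limb,
        "day": float(day),
        "true_cal_slope": TRUE_CAL_SLOPE,
        "true_cal_intercept": TRUE_CAL_INTERCEPT,
        "designed_bmd_g_cm3": callus_mean if limb == "treated" else CONTROL_BMD_G_CM3,
        "designed_csa_mm2": (
            truth.csa_pct(day) / 100.0 * CONTROL_CSA_MM2 if limb == "treated" else CONTROL_CSA_MM2
        ),
        "callus_radius_mm": callus_radius,
        "voxel_csa_mean_mm2": float(voxel_csa[in_defect_z].mean()),
        "voxel_tv_cm3": voxel_tv,
        "realized_bmd_g_cm3": realized_bmd,
    }
    meta = {
        "phantom_cylinders": phantom_meta,
        "roi_box": {"x_mm": list(ROI_BOX["x_mm"]), "y_mm": list(ROI_BOX["y_mm"])},
        "truth": truth_meta,
        "animal_id": truth.animal_id,
    }
    return ct.VoxelVolume(
        hu=hu, spacing=sp, defect_span=DEFECT_SPAN, origin=origin,
        phantoms=phantoms, roi_mask=roi, meta=meta,
    )
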