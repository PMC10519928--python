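"""Axial spring-network mechanics of an instrumented bone-fixator system.

A stabilized segmental bone defect is modeled as two parallel axial load
paths bridging the osteotomy: the external fixator (stiffness ``K_f``) and
the regenerating callus column (``K_c``), the latter in series with the
remaining proximal and distal cortical fragments (``K_bp``, ``K_bd``;
series-equivalent ``K_b``).  During stance the internal force ``F_i``
transmitted through the limb partitions into a fixator force ``F_f``
(measured by load cells in the connecting bars) and the callus force

    F_c = F_i - F_f.

``F_i`` itself is not measurable in vivo; it is estimated as a constant
ratio ``r`` of the peak ground reaction force, with ``r`` calibrated during
the early healing window when the callus path carries essentially no load
(``F_i ~= F_f``).  The apparent callus stiffness then follows from the
measured partition and the component stiffnesses:

    K_c = K_f * F_c * K_b / (F_f * K_b + F_c * K_f)

All stiffnesses are in N/mm, forces in N, times in days post-surgery.
``forward_load_partition`` is the exact algebraic inverse of the stiffness
formula; it drives the cohort simulator and the round-trip consistency
tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Axial stiffness of the Ilizarov-type external fixator (N/mm).
DEFAULT_FIXATOR_STIFFNESS = 593.0

#: Cortical bone elastic modulus used to derive fragment stiffness from
#: CT cross-section geometry (MPa; 21 GPa).
DEFAULT_CORTICAL_MODULUS = 21_000.0

#: Half-open day window [start, end) over which F_i ~= F_f is assumed and
#: the internal-force ratio is calibrated.
DEFAULT_CALIBRATION_WINDOW = (7.0, 14.0)

#: Below this fraction of F_i the fixator is considered unloaded and the
#: stiffness estimate is outside the calibrated measurement range.
DEFAULT_CENSOR_FRACTION = 0.02


class CalibrationError(ValueError):
    """Raised when the internal-force ratio cannot be calibrated."""


def series_equivalent_stiffness(k_bp: float, k_bd: float) -> float:
    """Equivalent stiffness of the two cortical fragments loaded in series.

    Parameters
    ----------
    k_bp, k_bd:
        Proximal and distal fragment axial stiffnesses (N/mm).

    Returns
    -------
    float
        ``k_bp * k_bd / (k_bp + k_bd)`` (N/mm); symmetric in its arguments
        and strictly below ``min(k_bp, k_bd)`` for finite inputs.
    """
    if not k_bp > 0:
        raise ValueError(f"k_bp must be > 0 N/mm, got {k_bp!r}")
    if not k_bd > 0:
        raise ValueError(f"k_bd must be > 0 N/mm, got {k_bd!r}")
    return (k_bp * k_bd) / (k_bp + k_bd)


def cortical_stiffness_from_profile(
    areas_mm2: Sequence[float],
    slice_thickness_mm: float | Sequence[float],
    e_modulus_mpa: float = DEFAULT_CORTICAL_MODULUS,
) -> float:
    """Axial stiffness of a varying-section rod from a per-slice area profile.

    The fragment is treated as a stack of short axial elements in series,
    one per CT slice: ``K = [ sum_z dz / (E * A(z)) ]^-1``.  For a uniform
    section this reduces to ``E * A / L``.  Bending is neglected.

    Parameters
    ----------
    areas_mm2:
        Mineralized cross-sectional area per slice (mm^2); all positive.
    slice_thickness_mm:
        Slice thickness (mm), scalar or per-slice.
    e_modulus_mpa:
        Elastic modulus (MPa). Default 21 GPa cortical bone.
    """
    areas = np.asarray(areas_mm2, dtype=float)
    if areas.size == 0:
        raise ValueError("area profile must contain at least one slice")
    if not e_modulus_mpa > 0:
        raise ValueError(f"e_modulus_mpa must be > 0, got {e_modulus_mpa!r}")
    dz = np.broadcast_to(np.asarray(slice_thickness_mm, dtype=float), areas.shape)
    if np.any(dz <= 0):
        raise ValueError("slice thickness must be > 0 mm")
    bad = np.flatnonzero(areas <= 0)
    if bad.size:
        raise ValueError(f"non-positive cross-sectional area at slice {bad[0]}")
    compliance = float(np.sum(dz / (e_modulus_mpa * areas)))
    return 1.0 / compliance


@dataclass(frozen=True)
class StiffnessSet:
    """Component stiffnesses of one animal's bone-fixator system (N/mm).

    ``k_b`` is derived from the series formula when not supplied; when
    supplied it must satisfy the formula to 1e-9 relative.
    """

    k_bp: float
    k_bd: float
    k_f: float = DEFAULT_FIXATOR_STIFFNESS
    k_b: Optional[float] = None
    e_modulus: float = DEFAULT_CORTICAL_MODULUS

    def __post_init__(self) -> None:
        for name in ("k_bp", "k_bd", "k_f", "e_modulus"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        derived = series_equivalent_stiffness(self.k_bp, self.k_bd)
        if self.k_b is None:
            object.__setattr__(self, "k_b", derived)
        elif not math.isclose(self.k_b, derived, rel_tol=1e-9):
            raise ValueError(
                f"k_b={self.k_b!r} inconsistent with series formula value {derived!r}"
            )

    @classmethod
    def from_geometry(
        cls,
        proximal_areas_mm2: Sequence[float],
        distal_areas_mm2: Sequence[float],
        slice_thickness_mm: float,
        k_f: float = DEFAULT_FIXATOR_STIFFNESS,
        e_modulus: float = DEFAULT_CORTICAL_MODULUS,
    ) -> "StiffnessSet":
        """Build fragment stiffnesses from CT area profiles (axial rod model)."""
        k_bp = cortical_stiffness_from_profile(proximal_areas_mm2, slice_thickness_mm, e_modulus)
        k_bd = cortical_stiffness_from_profile(distal_areas_mm2, slice_thickness_mm, e_modulus)
        return cls(k_bp=k_bp, k_bd=k_bd, k_f=k_f, e_modulus=e_modulus)


@dataclass
class LoadState:
    """Simultaneous forces of one stance event (peak-synchronized, N)."""

    day: float
    grf: float
    f_f: float
    f_i: Optional[float] = None
    f_c: Optional[float] = None
    valid: bool = True

    def with_internal_force(self, r: float) -> "LoadState":
        """Return a copy with ``F_i = r * GRF`` and ``F_c = F_i - F_f``."""
        f_i = r * self.grf
        return LoadState(
            day=self.day, grf=self.grf, f_f=self.f_f,
            f_i=f_i, f_c=callus_force(f_i, self.f_f), valid=self.valid,
        )


@dataclass(frozen=True)
class CalibrationRatio:
    """Calibrated internal-force / GRF ratio over the early healing window."""

    r: float
    window: tuple[float, float]
    n_samples: int

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"calibration ratio must be > 0, got {self.r!r}")


def calibrate_force_ratio(
    states: Sequence[LoadState],
    window: tuple[float, float] = DEFAULT_CALIBRATION_WINDOW,
) -> CalibrationRatio:
    """Calibrate ``r = F_i / GRF`` from early-window treads.

    During the first two post-surgical weeks the callus carries essentially
    no load, so the fixator force approximates the internal force and the
    per-tread ratio ``F_f_peak / GRF_peak`` estimates ``r``.  The ratio is
    the mean over all treads whose day lies in the half-open ``window``;
    treads with non-positive GRF are skipped with a warning.
    """
    lo, hi = window
    ratios = []
    for s in states:
        if not (lo <= s.day < hi):
            continue
        if s.grf <= 0:
            logger.warning("skipping tread on day %.1f with GRF=%.3f <= 0", s.day, s.grf)
            continue
        ratios.append(s.f_f / s.grf)
    if not ratios:
        raise CalibrationError(
            f"no usable treads in calibration window [{lo}, {hi})"
        )
    return CalibrationRatio(r=float(np.mean(ratios)), window=(lo, hi), n_samples=len(ratios))


def callus_force(f_i: float, f_f: float) -> float:
    """Callus force ``F_c = F_i - F_f`` (N); conservation holds exactly."""
    return f_i - f_f


def callus_stiffness(f_f: float, f_c: float, k_f: float, k_b: float) -> Optional[float]:
    """Apparent callus stiffness from the measured force partition.

        K_c = K_f * F_c * K_b / (F_f * K_b + F_c * K_f)

    Returns ``None`` (censored/invalid, outside the measurement range)
    whenever ``F_f <= 0`` or ``F_c <= 0`` instead of a number.
    """
    if not k_f > 0:
        raise ValueError(f"k_f must be > 0, got {k_f!r}")
    if not k_b > 0:
        raise ValueError(f"k_b must be > 0, got {k_b!r}")
    if f_f <= 0 or f_c <= 0:
        return None
    return k_f * (f_c * k_b) / (f_f * k_b + f_c * k_f)


def estimate_callus_stiffness(
    f_i: float,
    f_f: float,
    k_f: float,
    k_b: float,
    censor_fraction: float = DEFAULT_CENSOR_FRACTION,
) -> tuple[Optional[float], str]:
    """Estimate ``K_c`` with measurement-range censoring.

    Returns ``(value, status)`` with status one of:

    - ``"ok"``: numeric estimate;
    - ``"censored"``: fixator essentially unloaded (``F_f`` below
      ``censor_fraction * F_i``): the stiffness is beyond the calibrated
      range and only a lower bound is known (right-censored);
    - ``"invalid"``: non-positive ``F_i`` or ``F_c`` (no estimate).
    """
    if f_i <= 0:
        return None, "invalid"
    f_c = callus_force(f_i, f_f)
    if f_f < censor_fraction * f_i:
        return None, "censored"
    if f_c <= 0:
        return None, "invalid"
    return callus_stiffness(f_f, f_c, k_f, k_b), "ok"


def forward_load_partition(
    f_i: float, k_c: float, k_f: float, k_b: float
) -> tuple[float, float]:
    """Partition the internal force between fixator and callus paths.

    Exact algebraic inverse of :func:`callus_stiffness`: the unique
    ``(F_f, F_c)`` with ``F_f + F_c = F_i`` whose partition maps back to
    ``K_c``.  The fixator load-share fraction is

        lambda = K_f (K_b - K_c) / (K_c K_b + K_f (K_b - K_c)),

    strictly decreasing in ``K_c`` with ``lambda(0) = 1`` and
    ``lambda = 1/2`` at ``K_c = K_f K_b / (K_b + K_f)``.

    Valid for ``0 <= K_c < K_b``; at ``K_c >= K_b`` the lumped model is
    outside its validity range and a :class:`ValueError` is raised.
    """
    if not k_f > 0:
        raise ValueError(f"k_f must be > 0, got {k_f!r}")
    if not k_b > 0:
        raise ValueError(f"k_b must be > 0, got {k_b!r}")
    if k_c < 0:
        raise ValueError(f"k_c must be >= 0, got {k_c!r}")
    if k_c >= k_b:
        raise ValueError(f"k_c={k_c!r} >= k_b={k_b!r}: outside model validity")
    if f_i < 0:
        raise ValueError(f"f_i must be >= 0, got {f_i!r}")
    lam = k_f * (k_b - k_c) / (k_c * k_b + k_f * (k_b - k_c))
    f_f = lam * f_i
    return f_f, f_i - f_f


def load_share_fraction(f_f: float, f_i: float) -> float:
    """Fraction of the internal force carried by the fixator, ``F_f / F_i``."""
    if f_i <= 0:
        raise ValueError(f"f_i must be > 0, got {f_i!r}")
    return f_f / f_i
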