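"""Phantom-calibrated CT morphometry of the regenerating callus.

Workflow: map Hounsfield units to apparent mineral density through a linear
fit against calibration phantom inserts of known density (0-0.8 g HA/cm^3),
threshold the calibrated volume to a mineralized-tissue mask inside a
region of interest, and reduce the mask to per-slice profiles along the
longitudinal (z) bone axis:

- CSA(z): mineralized cross-sectional area per slice (mm^2),
- BMD(z): mean mapped density over masked voxels per slice (g HA/cm^3),
- TV: integral of CSA over the defect span plus margins (default 10 mm on
  each side), in cm^3.

Treated-limb summaries are reported as percentages of the contralateral
(non-operated) limb over a matched 15 mm defect-equivalent span.

Volumes are stored as NIfTI with voxel spacing in the header; phantom
inserts, region of interest, defect span and any generator ground truth
live in a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_DENSITY_THRESHOLD = 0.15  # g HA/cm^3
DEFAULT_TV_MARGIN = 10.0  # mm on each side of the defect
DEFAULT_PHANTOM_DENSITIES = (0.0, 0.1, 0.2, 0.4, 0.6, 0.8)  # g HA/cm^3


class CalibrationError(ValueError):
    """Raised when the HU-to-density calibration is degenerate."""


@dataclass
class PhantomInsert:
    """One calibration insert: known density and its voxel mask."""

    label: str
    density: float  # g HA/cm^3
    mask: np.ndarray  # boolean, same shape as the HU grid

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 0.8:
            raise ValueError(
                f"phantom density must lie in [0, 0.8] g HA/cm^3, got {self.density!r}"
            )


@dataclass
class VoxelVolume:
    """HU voxel grid with spacing, axis convention and phantom regions.

    Axes are ``(x, y, z)`` with z the longitudinal bone axis.  Voxel
    indices are 0-based; physical positions refer to voxel centers:
    ``pos = origin + (index + 0.5) * spacing``.  ``defect_span`` is a
    half-open ``[z_start, z_end)`` interval in mm.
    """

    hu: np.ndarray
    spacing: tuple[float, float, float]
    defect_span: tuple[float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phantoms: list[PhantomInsert] = field(default_factory=list)
    roi_mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.ndim != 3:
            raise ValueError("hu must be a 3-D grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0, got {self.spacing!r}")
        z0, z1 = self.defect_span
        z_lo = self.origin[2]
        z_hi = self.origin[2] + self.hu.shape[2] * self.spacing[2]
        if not (z_lo <= z0 < z1 <= z_hi):
            raise ValueError(
                f"defect_span {self.defect_span!r} outside volume extent [{z_lo}, {z_hi}]"
            )

    @property
    def z_positions(self) -> np.ndarray:
        """Slice-center z positions (mm)."""
        nz = self.hu.shape[2]
        return self.origin[2] + (np.arange(nz) + 0.5) * self.spacing[2]

    def phantom_union_mask(self) -> np.ndarray:
        m = np.zeros(self.hu.shape, dtype=bool)
        for p in self.phantoms:
            m |= p.mask
        return m


@dataclass(frozen=True)
class CalibrationLine:
    """Linear HU -> density mapping: ``density = slope * HU + intercept``."""

    slope: float  # g HA/cm^3 per HU
    intercept: float  # g HA/cm^3
    r_squared: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise CalibrationError(f"calibration slope must be > 0, got {self.slope!r}")

    def density(self, hu: np.ndarray | float) -> np.ndarray | float:
        return self.slope * hu + self.intercept


@dataclass
class MorphometryProfile:
    """Per-slice morphometry plus defect-window summaries."""

    z_mm: np.ndarray
    csa_mm2: np.ndarray
    bmd_g_cm3: np.ndarray  # NaN where a slice has no mineralized voxels
    defect_span: tuple[float, float]
    tv_cm3: float
    csa_mean_mm2: float
    bmd_mean_g_cm3: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"z_mm": self.z_mm, "csa_mm2": self.csa_mm2, "bmd_g_cm3": self.bmd_g_cm3}
        )


def calibrate_hu_to_bmd(volume: VoxelVolume) -> CalibrationLine:
    """Fit the linear HU -> mineral-density map on the phantom inserts.

    Ordinary least squares of known insert density on the mean HU of each
    insert region.  Requires at least two inserts with distinct mean HU.
    """
    if len(volume.phantoms) < 2:
        raise CalibrationError(
            f"need >= 2 phantom regions, got {len(volume.phantoms)}"
        )
    mean_hu = np.array([float(volume.hu[p.mask].mean()) for p in volume.phantoms])
    rho = np.array([p.density for p in volume.phantoms])
    if np.ptp(mean_hu) < 1e-12:
        raise CalibrationError("phantom regions have identical mean HU; cannot calibrate")
    fit = stats.linregress(mean_hu, rho)
    return CalibrationLine(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def segment_mineralized(
    volume: VoxelVolume,
    calibration: CalibrationLine,
    density_threshold: float = DEFAULT_DENSITY_THRESHOLD,
) -> np.ndarray:
    """Binary mask of voxels whose mapped density reaches the threshold.

    Phantom regions are always excluded; if the volume carries an ROI mask
    the result is restricted to it.  An empty mask is allowed.
    """
    density = calibration.density(volume.hu)
    mask = density >= density_threshold
    mask &= ~volume.phantom_union_mask()
    if volume.roi_mask is not None:
        mask &= volume.roi_mask
    return mask


def csa_profile(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Mineralized cross-sectional area per z-slice (mm^2)."""
    sx, sy = spacing[0], spacing[1]
    return mask.sum(axis=(0, 1)).astype(float) * (sx * sy)


def total_volume(
    z_mm: np.ndarray,
    csa_mm2: np.ndarray,
    slice_thickness_mm: float,
    defect_span: tuple[float, float],
    margin_mm: float = DEFAULT_TV_MARGIN,
) -> float:
    """Total mineralized volume (cm^3) over the defect plus margins.

    Rectangle-rule integral of CSA over slices whose center lies in
    ``[z_start - margin, z_end + margin)``; a window extending beyond the
    scanned extent is clipped with a warning.
    """
    z = np.asarray(z_mm, dtype=float)
    lo = defect_span[0] - margin_mm
    hi = defect_span[1] + margin_mm
    if lo < z[0] - 0.5 * slice_thickness_mm or hi > z[-1] + 0.5 * slice_thickness_mm:
        warnings.warn(
            f"TV window [{lo}, {hi}) mm extends beyond scanned extent; clipping",
            stacklevel=2,
        )
    sel = (z >= lo) & (z < hi)
    return float(np.sum(np.asarray(csa_mm2)[sel]) * slice_thickness_mm / 1000.0)


def bmd_profile(
    volume: VoxelVolume,
    mask: np.ndarray,
    calibration: CalibrationLine,
) -> tuple[np.ndarray, float]:
    """Per-slice and defect-span mean mineral density over masked voxels.

    Slices with no masked voxels yield NaN (missing), not zero.  The
    summary is the voxel-weighted mean density over the defect span; if
    the span holds no masked voxels the summary is NaN with a warning.
    """
    density = calibration.density(volume.hu)
    nz = volume.hu.shape[2]
    per_slice = np.full(nz, np.nan)
    for k in range(nz):
        m = mask[:, :, k]
        if m.any():
            per_slice[k] = float(density[:, :, k][m].mean())
    z = volume.z_positions
    in_span = (z >= volume.defect_span[0]) & (z < volume.defect_span[1])
    span_mask = mask & in_span[np.newaxis, np.newaxis, :]
    if not span_mask.any():
        warnings.warn("no mineralized voxels inside the defect span", stacklevel=2)
        return per_slice, float("nan")
    return per_slice, float(density[span_mask].mean())


def morphometry(
    volume: VoxelVolume,
    calibration: Optional[CalibrationLine] = None,
    density_threshold: float = DEFAULT_DENSITY_THRESHOLD,
    margin_mm: float = DEFAULT_TV_MARGIN,
) -> MorphometryProfile:
    """Full per-volume morphometry: calibrate, segment, profile, summarize."""
    if calibration is None:
        calibration = calibrate_hu_to_bmd(volume)
    mask = segment_mineralized(volume, calibration, density_threshold)
    csa = csa_profile(mask, volume.spacing)
    z = volume.z_positions
    dz = volume.spacing[2]
    tv = total_volume(z, csa, dz, volume.defect_span, margin_mm)
    bmd_slices, bmd_mean = bmd_profile(volume, mask, calibration)
    in_span = (z >= volume.defect_span[0]) & (z < volume.defect_span[1])
    csa_mean = float(csa[in_span].mean()) if in_span.any() else float("nan")
    return MorphometryProfile(
        z_mm=z,
        csa_mm2=csa,
        bmd_g_cm3=bmd_slices,
        defect_span=volume.defect_span,
        tv_cm3=tv,
        csa_mean_mm2=csa_mean,
        bmd_mean_g_cm3=bmd_mean,
    )


def normalize_to_contralateral(
    treated: MorphometryProfile, control: MorphometryProfile
) -> dict[str, float]:
    """Express treated summaries as % of the contralateral reference.

    The control denominators use the control's defect-equivalent span:
    mean CSA and BMD over that span, and TV as mean CSA times the span
    length (the healthy limb has no overgrowth outside the span).
    """
    span_len = control.defect_span[1] - control.defect_span[0]
    control_tv = control.csa_mean_mm2 * span_len / 1000.0
    refs = {
        "tv_pct": (treated.tv_cm3, control_tv),
        "csa_pct": (treated.csa_mean_mm2, control.csa_mean_mm2),
        "bmd_pct": (treated.bmd_mean_g_cm3, control.bmd_mean_g_cm3),
    }
    out = {}
    for key, (num, den) in refs.items():
        if not den or not np.isfinite(den):
            raise ValueError(f"control reference for {key} is zero or missing")
        out[key] = 100.0 * num / den
    return out


# ---------------------------------------------------------------------------
# NIfTI + JSON sidecar I/O
# ---------------------------------------------------------------------------

def cylinder_mask(
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    origin: Sequence[float],
    center_xy: Sequence[float],
    radius_mm: float,
    z_range_mm: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Boolean mask of a z-aligned cylinder, voxel-center membership."""
    nx, ny, nz = shape
    x = origin[0] + (np.arange(nx) + 0.5) * spacing[0]
    y = origin[1] + (np.arange(ny) + 0.5) * spacing[1]
    z = origin[2] + (np.arange(nz) + 0.5) * spacing[2]
    r2 = (x[:, None] - center_xy[0]) ** 2 + (y[None, :] - center_xy[1]) ** 2
    disk = r2 <= radius_mm**2
    mask = np.repeat(disk[:, :, None], nz, axis=2)
    if z_range_mm is not None:
        in_z = (z >= z_range_mm[0]) & (z < z_range_mm[1])
        mask &= in_z[None, None, :]
    return mask


def box_mask(
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    origin: Sequence[float],
    x_mm: tuple[float, float],
    y_mm: tuple[float, float],
) -> np.ndarray:
    """Boolean mask of an axis-aligned x/y box spanning all z."""
    nx, ny, nz = shape
    x = origin[0] + (np.arange(nx) + 0.5) * spacing[0]
    y = origin[1] + (np.arange(ny) + 0.5) * spacing[1]
    inx = (x >= x_mm[0]) & (x < x_mm[1])
    iny = (y >= y_mm[0]) & (y < y_mm[1])
    return inx[:, None, None] & iny[None, :, None] & np.ones(nz, dtype=bool)[None, None, :]


def save_volume(volume: VoxelVolume, nifti_path: str | Path, sidecar_path: str | Path) -> None:
    """Write the HU grid as NIfTI and regions/metadata as a JSON sidecar.

    Phantom inserts and the ROI must be present in ``volume.meta`` as
    geometric definitions (``phantom_cylinders``, ``roi_box``) so the
    sidecar stays small; masks are rebuilt on load.
    """
    affine = np.diag([volume.spacing[0], volume.spacing[1], volume.spacing[2], 1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.hu.astype(np.float32), affine)
    nib.save(img, str(nifti_path))
    sidecar = {
        "spacing_mm": list(volume.spacing),
        "origin_mm": list(volume.origin),
        "defect_span_mm": list(volume.defect_span),
        **volume.meta,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def load_volume(nifti_path: str | Path, sidecar_path: str | Path) -> VoxelVolume:
    """Load a NIfTI volume plus its JSON sidecar into a :class:`VoxelVolume`."""
    img = nib.load(str(nifti_path))
    hu = np.asarray(img.get_fdata(), dtype=float)
    sidecar = json.loads(Path(sidecar_path).read_text())
    spacing = tuple(sidecar["spacing_mm"])
    origin = tuple(sidecar.get("origin_mm", (0.0, 0.0, 0.0)))
    phantoms = [
        PhantomInsert(
            label=p["label"],
            density=p["density_g_cm3"],
            mask=cylinder_mask(hu.shape, spacing, origin, p["center_xy_mm"], p["radius_mm"]),
        )
        for p in sidecar.get("phantom_cylinders", [])
    ]
    roi = None
    if "roi_box" in sidecar:
        roi = box_mask(
            hu.shape, spacing, origin,
            tuple(sidecar["roi_box"]["x_mm"]), tuple(sidecar["roi_box"]["y_mm"]),
        )
    return VoxelVolume(
        hu=hu,
        spacing=spacing,
        defect_span=tuple(sidecar["defect_span_mm"]),
        origin=origin,
        phantoms=phantoms,
        roi_mask=roi,
        meta=sidecar,
    )
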