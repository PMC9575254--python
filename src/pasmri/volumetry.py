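"""Cavalieri-style volumetry of dark intraplacental bands (DIB).

On each imaging plane the lesion volume is estimated from the outlined
region-of-interest (ROI) areas of consecutive slices,

    V_p = (thickness_p + gap_p) * sum_i S_pi        [mm^3]

where ``thickness_p`` is the slice thickness, ``gap_p`` the inter-slice gap
and ``S_pi`` the ROI area on slice ``i``.  The per-subject estimate is the
mean of the three orthogonal planes,

    V_DIB = (V_axial + V_sagittal + V_coronal) / 3

and, when two radiologists outline independently, the final value is the
mean of their two per-subject estimates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

PLANES = ("axial", "sagittal", "coronal")


@dataclass
class SliceStack:
    """Ordered ROI slices of one imaging plane.

    Parameters
    ----------
    plane
        One of ``axial``, ``sagittal``, ``coronal``.
    thickness_mm
        Slice thickness, mm (> 0).
    gap_mm
        Inter-slice gap, mm (>= 0).
    areas_mm2
        Per-slice ROI areas S_pi in acquisition order; zero for slices with
        no delineated lesion (zeros are retained, they are neutral in the
        slice sum).
    masks
        Optional per-slice binary ROIs.  When present, each area must equal
        pixel count x pixel area.
    in_plane_spacing_mm
        Pixel edge lengths of the masks, mm.
    """

    plane: str
    thickness_mm: float
    gap_mm: float
    areas_mm2: np.ndarray
    masks: Optional[list] = None
    in_plane_spacing_mm: Optional[tuple] = None

    def __post_init__(self):
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}; expected one of {PLANES}")
        if self.thickness_mm <= 0:
            raise ValueError("slice thickness must be > 0 mm")
        if self.gap_mm < 0:
            raise ValueError("slice gap must be >= 0 mm")
        self.areas_mm2 = np.asarray(self.areas_mm2, dtype=float)
        if self.areas_mm2.ndim != 1:
            raise ValueError("areas must be a 1-D sequence")
        if np.any(self.areas_mm2 < 0):
            raise ValueError("ROI areas must be >= 0 mm^2")
        if self.masks is not None:
            if self.in_plane_spacing_mm is None:
                raise ValueError("masks require in_plane_spacing_mm")
            if len(self.masks) != len(self.areas_mm2):
                raise ValueError("one mask per slice required")
            px = float(np.prod(self.in_plane_spacing_mm))
            for a, m in zip(self.areas_mm2, self.masks):
                if abs(a - int(np.count_nonzero(m)) * px) > 1e-6 * max(1.0, a):
                    raise ValueError("area inconsistent with mask pixel count")

    @property
    def n_slices(self) -> int:
        return len(self.areas_mm2)

    @property
    def period_mm(self) -> float:
        """Slice-to-slice spacing, thickness + gap."""
        return self.thickness_mm + self.gap_mm

    @classmethod
    def from_masks(cls, plane, thickness_mm, gap_mm, masks, in_plane_spacing_mm):
        px = float(np.prod(in_plane_spacing_mm))
        areas = np.array([np.count_nonzero(m) * px for m in masks], dtype=float)
        return cls(plane, thickness_mm, gap_mm, areas,
                   masks=list(masks), in_plane_spacing_mm=tuple(in_plane_spacing_mm))


@dataclass(frozen=True)
class DIBVolumeEstimate:
    """Per-plane DIB volumes and their three-plane mean, mm^3."""

    v_axial: float
    v_sagittal: float
    v_coronal: float
    per_rater: Optional[tuple] = None

    def __post_init__(self):
        for v in (self.v_axial, self.v_sagittal, self.v_coronal):
            if v < 0:
                raise ValueError("plane volumes must be >= 0")

    @property
    def v_dib(self) -> float:
        return (self.v_axial + self.v_sagittal + self.v_coronal) / 3.0

    @property
    def final(self) -> float:
        """Rater-averaged volume when two raters are recorded, else v_dib."""
        if self.per_rater is not None:
            return float(np.mean(self.per_rater))
        return self.v_dib


def plane_volume(stack: SliceStack) -> float:
    """Single-plane slice-summation volume (thickness + gap) * sum of areas.

    Returns 0 for an empty stack or all-zero areas.
    """
    if stack.n_slices == 0:
        return 0.0
    return float(stack.period_mm * np.sum(stack.areas_mm2))


def dib_volume(axial: SliceStack, sagittal: SliceStack,
               coronal: SliceStack) -> DIBVolumeEstimate:
    """Three-plane DIB volume estimate for one subject.

    All three orthogonal planes are required; the estimator is not rescaled
    for missing planes.
    """
    for stack, name in ((axial, "axial"), (sagittal, "sagittal"), (coronal, "coronal")):
        if stack is None:
            raise ValueError(f"missing {name} stack: all three planes are required")
        if stack.plane != name:
            raise ValueError(f"stack passed as {name} is labelled {stack.plane!r}")
    return DIBVolumeEstimate(
        v_axial=plane_volume(axial),
        v_sagittal=plane_volume(sagittal),
        v_coronal=plane_volume(coronal),
    )


def rater_average(estimate_r1: DIBVolumeEstimate,
                  estimate_r2: DIBVolumeEstimate) -> DIBVolumeEstimate:
    """Average the per-subject volumes of two independent readers.

    The returned estimate carries the two per-rater v_dib values; its
    ``final`` is their mean.  Per-plane fields are plane-wise means so the
    v_dib identity still holds exactly.
    """
    return DIBVolumeEstimate(
        v_axial=(estimate_r1.v_axial + estimate_r2.v_axial) / 2.0,
        v_sagittal=(estimate_r1.v_sagittal + estimate_r2.v_sagittal) / 2.0,
        v_coronal=(estimate_r1.v_coronal + estimate_r2.v_coronal) / 2.0,
        per_rater=(estimate_r1.v_dib, estimate_r2.v_dib),
    )


# ---------------------------------------------------------------------------
# CSV interchange


def write_subject_csv(path, estimate: DIBVolumeEstimate, subject_id: str = "sub01"):
    """One-row CSV: subject, v_axial, v_sagittal, v_coronal, v_dib, final."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject", "v_axial_mm3", "v_sagittal_mm3",
                    "v_coronal_mm3", "v_dib_mm3", "final_mm3"])
        w.writerow([subject_id,
                    f"{estimate.v_axial:.6f}", f"{estimate.v_sagittal:.6f}",
                    f"{estimate.v_coronal:.6f}", f"{estimate.v_dib:.6f}",
                    f"{estimate.final:.6f}"])


def read_areas_csv(path, geometries) -> dict:
    """Read per-slice areas (columns: plane, slice_index, area_mm2).

    ``geometries`` maps plane name -> AcquisitionGeometry supplying the
    thickness and gap.  Returns a dict plane -> SliceStack.
    """
    rows: dict = {p: {} for p in PLANES}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            plane = rec["plane"].strip().lower()
            if plane not in PLANES:
                raise ValueError(f"unknown plane {plane!r} in {path}")
            rows[plane][int(rec["slice_index"])] = float(rec["area_mm2"])
    stacks = {}
    for plane, by_idx in rows.items():
        if not by_idx:
            continue
        geom = geometries[plane]
        n = max(by_idx) + 1
        areas = np.zeros(n)
        for i, a in by_idx.items():
            areas[i] = a
        stacks[plane] = SliceStack(plane, geom.slice_thickness, geom.slice_gap, areas)
    return stacks
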