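"""Ordinal grading of myometrial thickness (MT) on placental MRI.

The myometrium overlying the placental bed thins as gestation advances and
as chorionic invasion deepens.  Because a thickness close to the voxel size
cannot be measured reliably, measurements are graded against L_min, the
shortest edge length of the MRI voxel (1.5-2.0 mm for typical placental
protocols):

* ``G0`` - the myometrium shows a focal interruption (not measurable);
* ``G1`` - continuous, but the thinnest site measures below L_min;
* ``G2`` - continuous with the thinnest site at or above L_min.

The ordinal coding G0=0 < G1=1 < G2=2 is fixed package-wide: higher grade
means thicker (better preserved) myometrium, hence *lower* expected blood
loss, which fixes the sign conventions of the correlation and ROC analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Optional, Sequence

import numpy as np

from .phantom import AcquisitionGeometry, Phantom3D


class Grade(IntEnum):
    """MT grade; integer value is the repo-wide ordinal code."""

    G0 = 0
    G1 = 1
    G2 = 2


@dataclass(frozen=True)
class MTMeasurement:
    """Repeated thinnest-site thickness measurements for one subject.

    ``thinnest_values`` are treated as an unordered set of repeats (the
    protocol does not distinguish per-plane from per-repeat values).
    """

    continuous: bool
    thinnest_values: tuple
    l_min: float

    def __post_init__(self):
        if self.l_min <= 0:
            raise ValueError("l_min must be > 0 mm")
        object.__setattr__(self, "thinnest_values",
                           tuple(float(v) for v in self.thinnest_values))
        if self.continuous and len(self.thinnest_values) == 0:
            raise ValueError("continuous myometrium requires at least one measurement")

    @property
    def mean_thickness(self) -> Optional[float]:
        if not self.thinnest_values:
            return None
        return float(np.mean(self.thinnest_values))


@dataclass(frozen=True)
class MTGrade:
    """Assigned grade plus the mean thickness that produced it (None for G0)."""

    grade: Grade
    mean_thickness: Optional[float]
    l_min: float


def compute_l_min(geometries: Iterable[AcquisitionGeometry]) -> float:
    """Shortest voxel edge length across all acquired planes, mm.

    The most conservative reading of "shortest edge of the MRI voxel":
    the minimum over every plane of both in-plane pixel edges and the slice
    thickness.
    """
    geometries = list(geometries)
    if not geometries:
        raise ValueError("at least one acquisition geometry is required")
    return float(min(min(g.voxel_edges) for g in geometries))


def grade_mt(measurement: MTMeasurement) -> MTGrade:
    """Grade one subject's measurement set.

    An interrupted myometrium is G0 regardless of any recorded values; a
    mean thickness exactly equal to L_min grades G2 (the boundary belongs
    to the upper grade).
    """
    if not measurement.continuous:
        return MTGrade(Grade.G0, None, measurement.l_min)
    mean = measurement.mean_thickness
    if mean < measurement.l_min:
        return MTGrade(Grade.G1, mean, measurement.l_min)
    return MTGrade(Grade.G2, mean, measurement.l_min)


def consensus_grade(grade_r1: MTGrade, grade_r2: MTGrade,
                    extra: Optional[MTMeasurement] = None) -> MTGrade:
    """Deterministic stand-in for the two-reader negotiation step.

    Rules (symmetric in the two readers):

    1. identical grades are returned as-is;
    2. an interruption seen by either reader dominates (G0);
    3. a G1/G2 split is re-graded on the pooled measurement set: the
       ``extra`` measurement (both readers' values plus any additional
       repeats) when provided, else the mean of the two readers' means.

    Real readers negotiate; this rule is an explicit, reproducible proxy.
    """
    if grade_r1.grade == grade_r2.grade:
        # keep the pooled mean when both measured
        if grade_r1.grade is Grade.G0:
            return MTGrade(Grade.G0, None, grade_r1.l_min)
        mean = float(np.mean([grade_r1.mean_thickness, grade_r2.mean_thickness]))
        return MTGrade(grade_r1.grade, mean, grade_r1.l_min)
    if Grade.G0 in (grade_r1.grade, grade_r2.grade):
        return MTGrade(Grade.G0, None, grade_r1.l_min)
    if extra is not None:
        return grade_mt(extra)
    pooled = MTMeasurement(
        continuous=True,
        thinnest_values=(grade_r1.mean_thickness, grade_r2.mean_thickness),
        l_min=grade_r1.l_min,
    )
    return grade_mt(pooled)


def measure_thinnest(phantom: Phantom3D, l_min: float,
                     noise_sd: float = 0.2, n_repeats: int = 3,
                     seed: int = 0) -> MTMeasurement:
    """Simulate a reader measuring the phantom's thinnest myometrial site.

    Each repeat is the true minimum thickness plus independent Gaussian
    reading error of standard deviation ``noise_sd`` mm.  An interrupted
    shell yields ``continuous=False`` (grades G0 downstream); the repeat
    count is configurable because protocols differ on how many repeats
    enter the average (default 3).
    """
    rng = np.random.default_rng(seed)
    if phantom.interrupted:
        return MTMeasurement(continuous=False, thinnest_values=(), l_min=l_min)
    values = phantom.true_min_thickness + rng.normal(0.0, noise_sd, size=n_repeats)
    return MTMeasurement(continuous=True, thinnest_values=tuple(values), l_min=l_min)
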