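"""Region refinement: morphological opening, connected components, size filter,
and the subject-level patient/control call.

The refinement order is fixed: opening (removes isolated noise voxels and
separates weakly connected clusters), connected-component labeling, then
removal of components smaller than a physical volume threshold Ts (in mm^3,
converted to a voxel count via the working spacing). A subject is called a
patient when any positive voxel survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .voting import LabelVolume

__all__ = ["RegionInfo", "RegionSet", "SubjectCall", "morphological_opening",
           "connected_regions", "filter_small_regions", "subject_call",
           "ts_voxel_count", "refine"]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class RegionInfo:
    region_id: int
    voxel_count: int
    volume_mm3: float
    bbox: tuple[slice, slice, slice]
    centroid: tuple[float, float, float]


@dataclass
class RegionSet:
    """Connected positive regions of a label volume."""

    regions: list[RegionInfo]
    labeled: np.ndarray          # int array, 0 = background
    source: LabelVolume
    spacing: tuple[float, float, float]

    def to_frame(self, subject_id: str = "") -> pd.DataFrame:
        rows = [{
            "subject_id": subject_id,
            "region_id": r.region_id,
            "voxel_count": r.voxel_count,
            "volume_mm3": r.volume_mm3,
            "centroid_x": r.centroid[0],
            "centroid_y": r.centroid[1],
            "centroid_z": r.centroid[2],
        } for r in self.regions]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SubjectCall:
    subject_id: str
    is_patient_pred: bool
    surviving_regions: RegionSet


def morphological_opening(labels: LabelVolume, lw: int = 3) -> LabelVolume:
    """Binary opening with a cubic lw^3 structuring element.

    Anti-extensive (output within input) and idempotent; lw=1 is the identity.
    """
    if lw < 1 or lw % 2 == 0:
        raise ValueError("Lw must be odd and >= 1")
    if lw == 1:
        return labels
    structure = np.ones((lw,) * 3, dtype=bool)
    opened = ndimage.binary_opening(labels.labels.astype(bool), structure=structure)
    return LabelVolume(labels=opened.astype(np.uint8),
                       classifier_id=labels.classifier_id,
                       domain_mask=labels.domain_mask)


def connected_regions(labels: LabelVolume,
                      spacing: Sequence[float],
                      connectivity: int = 26) -> RegionSet:
    """Label maximal connected components of the positive set."""
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labeled, n = ndimage.label(labels.labels, structure=structure)
    voxvol = float(np.prod(spacing))
    regions = []
    if n:
        counts = np.bincount(labeled.ravel())
        slices = ndimage.find_objects(labeled)
        centroids = ndimage.center_of_mass(labels.labels, labeled, range(1, n + 1))
        for rid in range(1, n + 1):
            regions.append(RegionInfo(
                region_id=rid,
                voxel_count=int(counts[rid]),
                volume_mm3=float(counts[rid]) * voxvol,
                bbox=slices[rid - 1],
                centroid=tuple(float(c) for c in centroids[rid - 1]),
            ))
    return RegionSet(regions=regions, labeled=labeled, source=labels,
                     spacing=tuple(float(s) for s in spacing))


def ts_voxel_count(ts_mm3: float, spacing: Sequence[float]) -> float:
    """Convert a physical size threshold to the equivalent voxel count."""
    return float(ts_mm3) / float(np.prod(spacing))


def filter_small_regions(regions: RegionSet, ts_mm3: float) -> LabelVolume:
    """Drop connected regions with physical volume below Ts (mm^3).

    Every surviving component has volume >= Ts; survivors are untouched.
    """
    if ts_mm3 < 0:
        raise ValueError("Ts must be >= 0")
    keep_ids = [r.region_id for r in regions.regions if r.volume_mm3 >= ts_mm3]
    out = np.isin(regions.labeled, keep_ids) if keep_ids else np.zeros(
        regions.labeled.shape, dtype=bool)
    return LabelVolume(labels=out.astype(np.uint8),
                       classifier_id=regions.source.classifier_id,
                       domain_mask=regions.source.domain_mask)


def subject_call(refined: LabelVolume, subject_id: str,
                 regions: RegionSet | None = None,
                 spacing: Sequence[float] = (1.0, 1.0, 1.0),
                 connectivity: int = 26) -> SubjectCall:
    """Patient/control verdict: patient iff any positive voxel survives."""
    if regions is None:
        regions = connected_regions(refined, spacing, connectivity)
    return SubjectCall(subject_id=subject_id,
                       is_patient_pred=bool(refined.labels.any()),
                       surviving_regions=regions)


def refine(labels: LabelVolume, spacing: Sequence[float], lw: int = 3,
           ts_mm3: float = 112.5, connectivity: int = 26
           ) -> tuple[LabelVolume, LabelVolume, RegionSet]:
    """Full refinement: opening -> labeling -> size filter.

    Returns (opened, filtered, surviving region set).
    """
    opened = morphological_opening(labels, lw)
    regions = connected_regions(opened, spacing, connectivity)
    filtered = filter_small_regions(regions, ts_mm3)
    surviving = connected_regions(filtered, spacing, connectivity)
    return opened, filtered, surviving
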