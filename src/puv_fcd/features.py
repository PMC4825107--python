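"""Voxelwise FCD feature maps, the healthy-control normative model, and
feature grouping.

Four feature maps are computed per subject:

* F1 - GM thickness (mm): paired Euclidean distance transforms on the GM mask
  (distance to the nearest WM-side non-GM voxel plus distance to the nearest
  CSF-side non-GM voxel, minus one voxel). A deliberate simplification of
  PDE-based cortical thickness; it has the same monotone response to
  thickening.
* F2 - gradient magnitude (intensity/mm): central differences per axis.
* F3 - relative intensity: 1 - |Bg - I|/Bg clipped to [0,1], where Bg is the
  GM/WM boundary intensity (midpoint of the GM and WM histogram peaks).
  Maximal where intensity sits at the junction value, so blurred or
  signal-shifted lesional tissue scores high.
* F4 - GM/WM boundary width (mm): thickness of the partial-volume transition
  zone 0.1 < pv_wm < 0.9; a blurred junction widens the zone.

The normative model is the boxcar-window mean of each feature map averaged
over healthy controls; the feature difference is the voxelwise subtraction of
a subject's map from the normative map. Feature groups FG1-FG6 are fixed
subsets of {F1..F4, Fd1..Fd4}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import Volume, find_gm_wm_peaks, inbrain_histogram

__all__ = [
    "FEATURE_GROUPS", "FeatureMaps", "NormativeModel",
    "gm_thickness_map", "gradient_map", "relative_intensity_map",
    "gwb_width_map", "boundary_intensity", "normative_mean",
    "feature_difference", "assemble_feature_matrix", "select_best_group",
    "domain_mask",
]

FEATURE_NAMES = ("F1", "F2", "F3", "F4")

# Table of feature groups: FG1-3 use raw features, FG4-6 the corresponding
# normative differences.
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "FG1": ("F1", "F2", "F3"),
    "FG2": ("F1", "F2", "F3", "F4"),
    "FG3": ("F1", "F3", "F4"),
    "FG4": ("Fd1", "Fd2", "Fd3"),
    "FG5": ("Fd1", "Fd2", "Fd3", "Fd4"),
    "FG6": ("Fd1", "Fd3", "Fd4"),
}


def _voxel_edge_mm(spacing: Sequence[float]) -> float:
    return float(np.prod(spacing) ** (1.0 / 3.0))


def gm_thickness_map(pv_gm: Volume, pv_wm: Volume,
                     gm_threshold: float = 0.5) -> Volume:
    """GM thickness (F1) in mm on the GM mask (pv_gm >= threshold).

    thickness(v) = dist(v, nearest WM voxel) + dist(v, nearest non-GM non-WM
    voxel) - one voxel edge, clipped at 0; 0 outside the GM mask. Falls back
    to the plain non-GM distance on both sides if no WM voxels exist.
    """
    gm = pv_gm.data >= gm_threshold
    if not gm.any():
        raise ValueError("empty GM mask")
    wm = (pv_wm.data >= gm_threshold) & ~gm
    other = ~gm & ~wm
    spacing = pv_gm.spacing
    if wm.any():
        d_wm = ndimage.distance_transform_edt(~wm, sampling=spacing)
    else:
        d_wm = ndimage.distance_transform_edt(gm, sampling=spacing)
    if other.any():
        d_other = ndimage.distance_transform_edt(~other, sampling=spacing)
    else:
        d_other = ndimage.distance_transform_edt(gm, sampling=spacing)
    thickness = np.clip(d_wm + d_other - _voxel_edge_mm(spacing), 0.0, None)
    return pv_gm.with_data(np.where(gm, thickness, 0.0))


def gradient_map(vol: Volume) -> Volume:
    """Gradient magnitude (F2): Euclidean norm of per-axis central differences."""
    grads = np.gradient(vol.data, *vol.spacing)
    mag = np.sqrt(sum(g * g for g in grads))
    return vol.with_data(mag)


def boundary_intensity(vol: Volume) -> float:
    """GM/WM boundary intensity Bg: midpoint of the GM and WM histogram peaks."""
    hist, edges = inbrain_histogram(vol)
    lo, hi, _ = find_gm_wm_peaks(hist)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(0.5 * (centers[lo] + centers[hi]))


def relative_intensity_map(vol: Volume, bg: float) -> Volume:
    """Relative intensity (F3): 1 - |Bg - I|/Bg, clipped to [0, 1]."""
    if bg <= 0:
        raise ValueError("boundary intensity Bg must be positive")
    ri = np.clip(1.0 - np.abs(bg - vol.data) / bg, 0.0, 1.0)
    return vol.with_data(ri)


def gwb_zone(pv_gm: Volume, pv_wm: Volume,
             lo: float = 0.1, hi: float = 0.9) -> np.ndarray:
    """The GM/WM transition zone: partial WM fraction next to GM."""
    return (pv_wm.data > lo) & (pv_wm.data < hi) & (pv_gm.data > 0)


def gwb_width_map(pv_gm: Volume, pv_wm: Volume,
                  lo: float = 0.1, hi: float = 0.9) -> Volume:
    """GM/WM boundary width (F4) in mm.

    Inside the transition zone, width = 2 x distance to the nearest non-zone
    voxel + one voxel edge; 0 outside the zone. A hard binary step has an
    empty zone and an all-zero map.
    """
    zone = gwb_zone(pv_gm, pv_wm, lo, hi)
    if not zone.any():
        warnings.warn("GWB transition zone is empty; F4 is all zero")
        return pv_gm.with_data(np.zeros(pv_gm.shape))
    d = ndimage.distance_transform_edt(zone, sampling=pv_gm.spacing)
    width = (2.0 * d + _voxel_edge_mm(pv_gm.spacing)) * zone
    return pv_gm.with_data(width)


def domain_mask(pv_gm: Volume, pv_wm: Volume,
                lo: float = 0.1, hi: float = 0.9) -> np.ndarray:
    """Classification domain: cortical or juxta-cortical voxels.

    Voxels with any GM fraction, or inside the GWB transition zone. Everything
    outside is labeled negative without entering any classifier.
    """
    return (pv_gm.data > 0) | gwb_zone(pv_gm, pv_wm, lo, hi)


@dataclass
class FeatureMaps:
    """The four feature maps of one subject plus its classification domain."""

    f1: Volume
    f2: Volume
    f3: Volume
    f4: Volume
    domain: np.ndarray

    def __post_init__(self):
        shape = self.f1.shape
        for v in (self.f2, self.f3, self.f4):
            if v.shape != shape:
                raise ValueError("feature maps must share the grid")
        if self.domain.shape != shape:
            raise ValueError("domain mask grid mismatch")
        # features are zero outside the classification domain
        for v in (self.f1, self.f2, self.f3, self.f4):
            v.data[~self.domain] = 0.0

    def map(self, name: str) -> np.ndarray:
        return {"F1": self.f1, "F2": self.f2, "F3": self.f3, "F4": self.f4}[name].data

    @classmethod
    def compute(cls, volume: Volume, pv_gm: Volume, pv_wm: Volume,
                bg: Optional[float] = None,
                zone_lo: float = 0.1, zone_hi: float = 0.9) -> "FeatureMaps":
        if bg is None:
            bg = boundary_intensity(volume)
        return cls(
            f1=gm_thickness_map(pv_gm, pv_wm),
            f2=gradient_map(volume),
            f3=relative_intensity_map(volume, bg),
            f4=gwb_width_map(pv_gm, pv_wm, zone_lo, zone_hi),
            domain=domain_mask(pv_gm, pv_wm, zone_lo, zone_hi),
        )


def _box_mean(data: np.ndarray, window_edge: int) -> np.ndarray:
    # truncated windows at the boundary, renormalized by actual window size
    num = ndimage.uniform_filter(data, size=window_edge, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(np.ones_like(data), size=window_edge,
                                 mode="constant", cval=0.0)
    return num / den


def normative_mean(control_maps: Sequence[np.ndarray | Volume],
                   window_edge: int = 3) -> np.ndarray:
    """Locally averaged healthy-control mean map F_mu.

    The boxcar mean over the window_edge^3 neighborhood of each voxel,
    averaged over the K control maps. Boundary voxels use the truncated
    window renormalized by its actual size. Linear in the inputs; the
    identity for K=1, window_edge=1.
    """
    if len(control_maps) < 1:
        raise ValueError("need at least one control map")
    if window_edge < 1 or window_edge % 2 == 0:
        raise ValueError("window_edge must be odd and >= 1")
    arrays = [m.data if isinstance(m, Volume) else np.asarray(m, dtype=float)
              for m in control_maps]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("control map grid mismatch")
    mean_map = np.mean(arrays, axis=0)
    if window_edge == 1:
        return mean_map
    return _box_mean(mean_map, window_edge)


@dataclass
class NormativeModel:
    """Per-feature normative maps F_mu built from K healthy controls."""

    f_mu: dict[str, np.ndarray]
    window_edge: int
    n_controls: int

    @classmethod
    def fit(cls, control_features: Sequence[FeatureMaps],
            window_edge: int = 3) -> "NormativeModel":
        if not control_features:
            raise ValueError("need at least one control")
        f_mu = {
            name: normative_mean([fm.map(name) for fm in control_features],
                                 window_edge)
            for name in FEATURE_NAMES
        }
        return cls(f_mu=f_mu, window_edge=window_edge,
                   n_controls=len(control_features))


def feature_difference(f: np.ndarray | Volume, f_mu: np.ndarray) -> np.ndarray:
    """Fd(v) = F(v) - F_mu(v); may be negative."""
    data = f.data if isinstance(f, Volume) else np.asarray(f, dtype=float)
    f_mu = np.asarray(f_mu, dtype=float)
    if data.shape != f_mu.shape:
        raise ValueError("grid mismatch between feature and normative map")
    return data - f_mu


def assemble_feature_matrix(features: FeatureMaps,
                            normative: Optional[NormativeModel],
                            group: str | Sequence[str],
                            mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Build the per-voxel feature matrix for one feature group.

    Returns (idx, X): idx is an (n, 3) array of voxel coordinates in
    lexicographic (x, y, z) order, X the (n, d) matrix with columns ordered
    as the group's members.
    """
    members = FEATURE_GROUPS[group] if isinstance(group, str) else tuple(group)
    if mask.shape != features.f1.shape:
        raise ValueError("mask grid mismatch")
    idx = np.argwhere(mask)
    cols = []
    for m in members:
        if m.startswith("Fd"):
            if normative is None:
                raise ValueError(f"group member {m} requires a normative model")
            base = "F" + m[2:]
            col = feature_difference(features.map(base), normative.f_mu[base])
        else:
            col = features.map(m)
        cols.append(col[mask])
    X = np.stack(cols, axis=1) if cols else np.zeros((idx.shape[0], 0))
    return idx, X


def _group_order(gid: str) -> int:
    return int(gid.removeprefix("FG"))


def select_best_group(per_group_scores: Mapping[str, Sequence[float]]) -> str:
    """Pick FG_best: the group with the highest classifier-averaged F-score.

    Ties break toward the smaller group index for determinism.
    """
    if not per_group_scores:
        raise ValueError("empty scores")
    lengths = {len(v) for v in per_group_scores.values()}
    if len(lengths) != 1 or lengths == {0}:
        raise ValueError("every group needs the same non-empty classifier list")
    best = None
    best_score = -np.inf
    for gid in sorted(per_group_scores, key=_group_order):
        a_ek = float(np.mean(per_group_scores[gid]))
        if a_ek > best_score:
            best, best_score = gid, a_ek
    return best
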