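"""NIfTI volume handling: intensity standardization, histogram-peak checks, resampling.

All volumes in a cohort are assumed pre-aligned (same grid shape and voxel
spacing); orientation and registration are out of scope.  In-brain voxels are
identified by strictly positive intensity, matching skull-stripped clinical
volumes and the phantom generator's zero background.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "Volume",
    "Subject",
    "load_volume",
    "save_volume",
    "load_cohort",
    "write_cohort",
    "standardize_intensity",
    "inbrain_histogram",
    "find_gm_wm_peaks",
    "histogram_peak_overlap",
    "resample_trilinear",
]

STANDARD_MAX = 255.0


@dataclass(frozen=True)
class Volume:
    """A 3D scalar grid with voxel spacing in mm.

    ``data`` is indexed (x, y, z), 0-based. Carries raw intensities,
    standardized intensities on the 0-255 scale, feature values, or
    probabilities depending on context.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={data.ndim}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains NaN/Inf")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data=data, spacing=self.spacing)


@dataclass
class Subject:
    """One cohort member: intensity volume, optional PV maps, optional lesion mask."""

    id: str
    volume: Volume
    pv_gm: Optional[Volume] = None
    pv_wm: Optional[Volume] = None
    pv_csf: Optional[Volume] = None
    lesion_mask: Optional[Volume] = None
    is_patient: bool = False

    def __post_init__(self):
        for name in ("pv_gm", "pv_wm", "pv_csf", "lesion_mask"):
            v = getattr(self, name)
            if v is None:
                continue
            if v.shape != self.volume.shape or not np.allclose(v.spacing, self.volume.spacing):
                raise ValueError(f"subject {self.id}: {name} grid mismatch")
        pvs = [v for v in (self.pv_gm, self.pv_wm, self.pv_csf) if v is not None]
        for v in pvs:
            if v.data.min() < -1e-9 or v.data.max() > 1 + 1e-6:
                raise ValueError(f"subject {self.id}: PV map outside [0,1]")
        if len(pvs) == 3:
            total = self.pv_gm.data + self.pv_wm.data + self.pv_csf.data
            if total.max() > 1 + 1e-6:
                raise ValueError(f"subject {self.id}: PV maps sum above 1")
        if self.lesion_mask is not None and self.lesion_mask.data.any() and not self.is_patient:
            raise ValueError(f"subject {self.id}: nonempty lesion mask requires is_patient")


# ---------------------------------------------------------------------------
# I/O

def load_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing)


def save_volume(vol: Volume, path: str | Path, dtype=np.float32) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


MANIFEST_COLUMNS = [
    "id", "path", "is_patient", "lesion_mask_path",
    "pv_gm_path", "pv_wm_path", "pv_csf_path",
]


def _maybe_load(base: Path, value) -> Optional[Volume]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value) == "":
        return None
    p = Path(str(value))
    if not p.is_absolute():
        p = base / p
    return load_volume(p)


def load_cohort(manifest_path: str | Path) -> list[Subject]:
    """Load a cohort from a manifest CSV; enforces a common grid."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype={"id": str})
    missing = [c for c in ("id", "path", "is_patient") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    base = manifest_path.parent
    subjects = []
    for row in df.itertuples(index=False):
        vol = _maybe_load(base, row.path)
        if vol is None:
            raise ValueError(f"subject {row.id}: missing volume path")
        sub = Subject(
            id=str(row.id),
            volume=vol,
            pv_gm=_maybe_load(base, getattr(row, "pv_gm_path", None)),
            pv_wm=_maybe_load(base, getattr(row, "pv_wm_path", None)),
            pv_csf=_maybe_load(base, getattr(row, "pv_csf_path", None)),
            lesion_mask=_maybe_load(base, getattr(row, "lesion_mask_path", None)),
            is_patient=bool(row.is_patient),
        )
        subjects.append(sub)
    if subjects:
        ref = subjects[0].volume
        for s in subjects[1:]:
            if s.volume.shape != ref.shape or not np.allclose(s.volume.spacing, ref.spacing):
                raise ValueError(f"subject {s.id}: grid differs from cohort grid")
    return subjects


def write_cohort(subjects: Sequence[Subject], out_dir: str | Path) -> Path:
    """Write volumes, masks and PV maps as NIfTI plus a manifest CSV.

    Returns the manifest path. Masks are stored as uint8 {0,1}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        row = {c: "" for c in MANIFEST_COLUMNS}
        row["id"] = s.id
        row["is_patient"] = s.is_patient
        vpath = f"{s.id}_t1.nii.gz"
        save_volume(s.volume, out_dir / vpath)
        row["path"] = vpath
        for name, col in (("pv_gm", "pv_gm_path"), ("pv_wm", "pv_wm_path"),
                          ("pv_csf", "pv_csf_path")):
            v = getattr(s, name)
            if v is not None:
                p = f"{s.id}_{name}.nii.gz"
                save_volume(v, out_dir / p)
                row[col] = p
        if s.lesion_mask is not None:
            p = f"{s.id}_lesion.nii.gz"
            save_volume(s.lesion_mask, out_dir / p, dtype=np.uint8)
            row["lesion_mask_path"] = p
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# Intensity standardization

def inbrain_mask(vol: Volume) -> np.ndarray:
    return vol.data > 0


def standardize_intensity(vol: Volume, lo: float = 1.0, hi: float = 99.0) -> Volume:
    """Two-point robust linear rescale of in-brain intensities to the 0-255 scale.

    The ``lo``/``hi`` percentiles of in-brain (positive) voxels map to 0/255;
    values beyond are clipped. Monotone non-decreasing in the input, idempotent
    to numerical tolerance, and invariant to affine input transforms a*x+b, a>0.

    In-brain voxels are kept strictly positive (clipped values are floored at
    a tiny epsilon) so the in-brain mask survives standardization, and a
    volume whose anchor percentiles already sit within half an intensity bin
    of 0/255 is returned unchanged - this makes repeated standardization the
    identity.
    """
    mask = inbrain_mask(vol)
    inb = vol.data[mask]
    if inb.size == 0:
        raise ValueError("degenerate intensity range: no in-brain voxels")
    p_lo, p_hi = np.percentile(inb, [lo, hi])
    if p_hi <= p_lo:
        raise ValueError("degenerate intensity range")
    if p_lo <= 0.5 and p_hi >= STANDARD_MAX - 0.5 and vol.data.max() <= STANDARD_MAX:
        return vol
    out = (vol.data - p_lo) * (STANDARD_MAX / (p_hi - p_lo))
    out = np.clip(out, 0.0, STANDARD_MAX)
    out[mask] = np.maximum(out[mask], 1e-9)
    out[~mask] = 0.0
    return vol.with_data(out)


# ---------------------------------------------------------------------------
# Histogram-peak overlap check

def inbrain_histogram(vol: Volume, bins: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Density-normalized histogram of in-brain voxels over [0, 255]."""
    values = vol.data[inbrain_mask(vol)]
    hist, edges = np.histogram(values, bins=bins, range=(0.0, STANDARD_MAX))
    total = hist.sum()
    if total == 0:
        raise ValueError("empty in-brain histogram")
    return hist / total, edges


def _smooth(hist: np.ndarray, width: int = 5) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(hist, kernel, mode="same")


def find_gm_wm_peaks(hist: np.ndarray, min_separation: int = 20,
                     smooth_width: int = 5) -> tuple[int, int, np.ndarray]:
    """Locate the GM and WM peaks of a (standardized) in-brain histogram.

    The histogram is smoothed by a moving average, and the two highest local
    maxima separated by at least ``min_separation`` bins are taken as the
    GM and WM peaks. Returns (low_peak_bin, high_peak_bin, support_window)
    where the boolean support window covers +/- 2 FWHM around each peak.
    """
    sm = _smooth(hist, smooth_width)
    peaks, props = signal.find_peaks(sm, height=0)
    if len(peaks) < 2:
        raise ValueError("bimodality not found")
    order = np.argsort(props["peak_heights"])[::-1]
    first = peaks[order[0]]
    second = None
    for idx in order[1:]:
        if abs(peaks[idx] - first) >= min_separation:
            second = peaks[idx]
            break
    if second is None:
        raise ValueError("bimodality not found")
    widths, _, _, _ = signal.peak_widths(
        sm, np.array([first, second]), rel_height=0.5)
    window = np.zeros(hist.shape, dtype=bool)
    for peak, fwhm in zip((first, second), widths):
        half = max(int(round(2 * fwhm)), 1)
        window[max(peak - half, 0): peak + half + 1] = True
    lo, hi = sorted((int(first), int(second)))
    return lo, hi, window


def histogram_peak_overlap(query: Volume, reference: Volume, bins: int = 256) -> float:
    """Histogram-intersection fraction between two standardized volumes.

    Both in-brain histograms are density-normalized; the intersection
    sum(min(hq, hr)) / sum(hr) is computed on the union of the GM/WM peak
    support windows of the reference. A query passes the normalization check
    when the returned fraction is >= 0.9.
    """
    for v in (query, reference):
        if v.data.min() < 0 or v.data.max() > STANDARD_MAX:
            raise ValueError("volumes must be standardized to [0,255]")
    hq, _ = inbrain_histogram(query, bins)
    hr, _ = inbrain_histogram(reference, bins)
    # precondition: both volumes show GM and WM peaks
    find_gm_wm_peaks(hq)
    _, _, window = find_gm_wm_peaks(hr)
    denom = hr[window].sum()
    if denom <= 0:
        raise ValueError("reference histogram empty on peak windows")
    return float(np.minimum(hq, hr)[window].sum() / denom)


# ---------------------------------------------------------------------------
# Resampling

def resample_trilinear(vol: Volume, target_spacing: Sequence[float]) -> Volume:
    """Resample to ``target_spacing`` (mm per axis) by trilinear interpolation.

    The output grid has shape ceil(extent / target_spacing); sample i along an
    axis sits at physical position i * target_spacing, so equal spacing is the
    identity. Values are interpolants of the input and stay within its range.
    """
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise ValueError("target_spacing must be positive")
    if np.allclose(target, vol.spacing):
        return vol
    extent = np.array(vol.shape) * np.array(vol.spacing)
    new_shape = np.ceil(extent / np.array(target) - 1e-9).astype(int)
    grids = [np.arange(n) * t / s for n, t, s in zip(new_shape, target, vol.spacing)]
    coords = np.meshgrid(*grids, indexing="ij")
    out = ndimage.map_coordinates(vol.data, coords, order=1, mode="nearest")
    return Volume(data=out, spacing=target)
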