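"""Synthetic pre-aligned brain phantoms with FCD-like cortical lesions.

Each phantom is a perturbed spherical shell: an inner white-matter ball, a
gray-matter ribbon of configurable thickness, and a thin outer CSF layer,
embedded in a zero background. The shell radius is modulated by a low-order
spherical-harmonic field (a crude stand-in for gyration) so that normative
feature maps are spatially non-uniform. Lesions carry the three radiological
signatures of focal cortical dysplasia: local cortical thickening, blurring
of the GM/WM junction, and a WM intensity shift toward the junction intensity
(which raises the relative-intensity feature, mimicking the lesional signal
change seen on T1).

Partial-volume maps are computed analytically by 3x3x3 subvoxel sampling, so
ground truth (tissue fractions and the lesion mask) is exact by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import erfc

from .volume_io import Subject, Volume

__all__ = ["LesionSpec", "PhantomConfig", "CohortConfig",
           "generate_subject", "generate_cohort"]


@dataclass(frozen=True)
class LesionSpec:
    """An FCD-like lesion patch: a ball (in mm) around a point on the ribbon.

    center is a (possibly fractional) voxel coordinate; radius_mm the patch
    radius. thickening_factor >= 1 multiplies the local ribbon thickness,
    junction_blur_sigma_mm smooths the local GM/WM transition, and
    wm_hyperintensity_shift moves in-patch WM intensity toward the junction
    intensity (subtracted from the WM mean, since WM is brighter than the
    junction on T1).
    """

    center: tuple[float, float, float]
    radius_mm: float = 6.0
    thickening_factor: float = 2.0
    junction_blur_sigma_mm: float = 2.0
    wm_hyperintensity_shift: float = 30.0

    def __post_init__(self):
        if self.thickening_factor < 1:
            raise ValueError("thickening_factor must be >= 1")
        if self.junction_blur_sigma_mm < 0 or self.wm_hyperintensity_shift < 0:
            raise ValueError("blur sigma and intensity shift must be >= 0")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    wm_mean: float = 160.0
    gm_mean: float = 110.0
    csf_mean: float = 30.0
    background: float = 0.0
    noise_sd: float = 4.0
    ribbon_thickness_mm: float = 3.0
    wm_radius_mm: float = 18.0
    csf_thickness_mm: float = 2.0
    gyral_amplitude: float = 0.08   # max relative radial modulation, <= 0.2
    lesion: Optional[LesionSpec] = None
    seed: int = 0
    # cohorts are pre-aligned: subjects share one anatomy (gyral field) unless
    # this is None, in which case the subject seed shapes the anatomy too
    gyral_seed: Optional[int] = None

    def __post_init__(self):
        if not (self.wm_mean > self.gm_mean > self.csf_mean >= 0):
            raise ValueError("T1 contrast ordering requires wm > gm > csf >= 0")
        if self.ribbon_thickness_mm <= 0:
            raise ValueError("ribbon_thickness_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.gyral_amplitude <= 0.2):
            raise ValueError("gyral_amplitude must be in [0, 0.2]")


# Real spherical harmonics (bands 2-4) in Cartesian form on the unit sphere.
_GYRAL_BASIS = (
    lambda x, y, z: x * y,
    lambda x, y, z: y * z,
    lambda x, y, z: x * z,
    lambda x, y, z: x * x - y * y,
    lambda x, y, z: 3 * z * z - 1.0,
    lambda x, y, z: x * y * z,
    lambda x, y, z: x * (5 * z * z - 1.0),
    lambda x, y, z: (x * x - 3 * y * y) * x,
    lambda x, y, z: (7 * z * z - 3.0) * x * y,
)


class _GyralField:
    """Seeded radial modulation g(u) with max |g| equal to the amplitude."""

    def __init__(self, rng: np.random.Generator, amplitude: float):
        self.coeffs = rng.standard_normal(len(_GYRAL_BASIS))
        if amplitude == 0:
            self.scale = 0.0
            return
        # normalize against a dense direction sample
        th = np.linspace(0, np.pi, 91)
        ph = np.linspace(0, 2 * np.pi, 181)
        T, P = np.meshgrid(th, ph, indexing="ij")
        ux = np.sin(T) * np.cos(P)
        uy = np.sin(T) * np.sin(P)
        uz = np.cos(T)
        peak = np.abs(self._raw(ux, uy, uz)).max()
        self.scale = amplitude / peak if peak > 0 else 0.0

    def _raw(self, ux, uy, uz):
        out = np.zeros(np.broadcast(ux, uy, uz).shape)
        for c, fn in zip(self.coeffs, _GYRAL_BASIS):
            out += c * fn(ux, uy, uz)
        return out

    def __call__(self, ux, uy, uz):
        if self.scale == 0.0:
            return np.zeros(np.broadcast(ux, uy, uz).shape)
        return self.scale * self._raw(ux, uy, uz)


_SQRT2 = np.sqrt(2.0)


def _grid_center_mm(cfg: PhantomConfig) -> np.ndarray:
    return (np.array(cfg.grid_shape) - 1) / 2.0 * np.array(cfg.spacing)


def generate_subject(cfg: PhantomConfig, subject_id: str = "phantom") -> Subject:
    """Generate one phantom Subject, deterministic in ``cfg.seed``.

    PV maps are subvoxel-exact tissue fractions; with noise_sd=0 the voxel
    intensity equals the PV-weighted sum of tissue means exactly. The lesion
    mask is the set of voxels whose PV vector changed by more than 0.01
    against the unlesioned twin, plus WM voxels receiving the intensity shift.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.gyral_seed is None:
        gyral = _GyralField(rng, cfg.gyral_amplitude)
    else:
        gyral = _GyralField(np.random.default_rng(cfg.gyral_seed),
                            cfg.gyral_amplitude)
    nx, ny, nz = cfg.grid_shape
    sx, sy, sz = cfg.spacing
    center = _grid_center_mm(cfg)

    lesion = cfg.lesion
    if lesion is not None:
        lc = np.array(lesion.center, dtype=float) * np.array(cfg.spacing)
        extent = (np.array(cfg.grid_shape) - 1) * np.array(cfg.spacing)
        if np.any(lc - lesion.radius_mm < 0) or np.any(lc + lesion.radius_mm > extent):
            raise ValueError("lesion patch clipped by grid boundary")
        d_center = np.linalg.norm(lc - center)
        band = cfg.ribbon_thickness_mm * lesion.thickening_factor + lesion.radius_mm
        if abs(d_center - cfg.wm_radius_mm) > band:
            raise ValueError("lesion patch does not lie on the cortical ribbon")

    # subvoxel offsets: 3 per axis at the subcell centers
    sub = (np.arange(3) - 1) / 3.0
    axes_mm = (np.arange(nx) * sx, np.arange(ny) * sy, np.arange(nz) * sz)

    pv = {t: np.zeros(cfg.grid_shape) for t in ("gm", "wm", "csf")}
    pv0 = {t: np.zeros(cfg.grid_shape) for t in ("gm", "wm", "csf")}

    for ox in sub * sx:
        dx = (axes_mm[0] + ox - center[0])[:, None, None]
        for oy in sub * sy:
            dy = (axes_mm[1] + oy - center[1])[None, :, None]
            for oz in sub * sz:
                dz = (axes_mm[2] + oz - center[2])[None, None, :]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                rsafe = np.where(r > 0, r, 1.0)
                g = gyral(dx / rsafe, dy / rsafe, dz / rsafe)
                r_wm = cfg.wm_radius_mm * (1.0 + g)

                if lesion is not None:
                    px = (axes_mm[0] + ox - lc[0])[:, None, None]
                    py = (axes_mm[1] + oy - lc[1])[None, :, None]
                    pz = (axes_mm[2] + oz - lc[2])[None, None, :]
                    in_patch = (px * px + py * py + pz * pz) <= lesion.radius_mm ** 2
                else:
                    in_patch = None

                def accumulate(target, thick, sigma):
                    gm_outer = r_wm + thick
                    if np.ndim(sigma) == 0 and sigma == 0:
                        u = (r < r_wm).astype(float)
                    else:
                        sig = np.where(sigma > 0, sigma, 1.0)
                        u = np.where(sigma > 0,
                                     0.5 * erfc((r - r_wm) / (sig * _SQRT2)),
                                     (r < r_wm).astype(float))
                    band = r < gm_outer
                    target["wm"] += u * band
                    target["gm"] += (1.0 - u) * band
                    target["csf"] += (~band) & (r < gm_outer + cfg.csf_thickness_mm)

                if lesion is None:
                    accumulate(pv0, cfg.ribbon_thickness_mm, 0.0)
                else:
                    thick = cfg.ribbon_thickness_mm * np.where(
                        in_patch, lesion.thickening_factor, 1.0)
                    sigma = np.where(in_patch, lesion.junction_blur_sigma_mm, 0.0)
                    accumulate(pv, thick, sigma)
                    accumulate(pv0, cfg.ribbon_thickness_mm, 0.0)

    if lesion is None:
        pv = pv0
    for maps in (pv, pv0) if lesion is not None else (pv,):
        for t in maps:
            maps[t] /= 27.0

    # lesion mask: PV change > 0.01 against the unlesioned twin, plus shifted WM
    voxel_patch = np.zeros(cfg.grid_shape, dtype=bool)
    if lesion is not None:
        vx = (axes_mm[0] - lc[0])[:, None, None]
        vy = (axes_mm[1] - lc[1])[None, :, None]
        vz = (axes_mm[2] - lc[2])[None, None, :]
        voxel_patch = (vx * vx + vy * vy + vz * vz) <= lesion.radius_mm ** 2
        delta = np.maximum.reduce([np.abs(pv[t] - pv0[t]) for t in pv])
        mask = delta > 0.01
        if lesion.wm_hyperintensity_shift > 0:
            mask |= voxel_patch & (pv["wm"] > 0.5)
    else:
        mask = np.zeros(cfg.grid_shape, dtype=bool)

    wm_intensity = cfg.wm_mean - (
        lesion.wm_hyperintensity_shift if lesion is not None else 0.0) * voxel_patch
    head = (pv["gm"] + pv["wm"] + pv["csf"]) > 0
    intensity = (pv["gm"] * cfg.gm_mean + pv["wm"] * wm_intensity
                 + pv["csf"] * cfg.csf_mean
                 + (1.0 - pv["gm"] - pv["wm"] - pv["csf"]) * cfg.background)
    if cfg.noise_sd > 0:
        noise = rng.normal(0.0, cfg.noise_sd, size=cfg.grid_shape)
        intensity = np.where(head, intensity + noise, intensity)
        intensity = np.clip(intensity, 0.0, 255.0)
        intensity[head] = np.maximum(intensity[head], 1e-3)

    return Subject(
        id=subject_id,
        volume=Volume(intensity, cfg.spacing),
        pv_gm=Volume(pv["gm"], cfg.spacing),
        pv_wm=Volume(pv["wm"], cfg.spacing),
        pv_csf=Volume(pv["csf"], cfg.spacing),
        lesion_mask=Volume(mask.astype(np.uint8), cfg.spacing),
        is_patient=bool(mask.any()),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Per-subject variation and lesion sampling ranges for cohort generation.

    Tissue means and ribbon thickness get Gaussian jitter per subject; patient
    lesions get a random location on the WM surface and severities drawn
    uniformly from the stated ranges (degenerate ranges fix the severity).
    """

    intensity_jitter_sd: float = 3.0
    thickness_jitter_sd: float = 0.15
    # patch radii chosen so lesion masks land near the few-thousand-mm^3
    # volume typical of clinically reported FCD lesions
    lesion_radius_range: tuple[float, float] = (8.0, 10.0)
    thickening_factor_range: tuple[float, float] = (2.0, 2.0)
    junction_blur_sigma_range: tuple[float, float] = (2.0, 2.0)
    wm_shift_range: tuple[float, float] = (30.0, 30.0)


def _uniform(rng, lohi):
    lo, hi = lohi
    return lo if lo == hi else float(rng.uniform(lo, hi))


def generate_cohort(n_controls: int, n_patients: int,
                    base_cfg: PhantomConfig | None = None,
                    seed: int = 0,
                    cohort_cfg: CohortConfig | None = None) -> list[Subject]:
    """Generate a reproducible cohort of controls followed by patients."""
    if n_controls < 0 or n_patients < 0:
        raise ValueError("counts must be >= 0")
    base = base_cfg if base_cfg is not None else PhantomConfig()
    cc = cohort_cfg if cohort_cfg is not None else CohortConfig()
    rng = np.random.default_rng(seed)
    # one shared anatomy: cohorts stand in for registered, pre-aligned scans
    gyral_seed = int(rng.integers(2 ** 31))
    subjects: list[Subject] = []
    roles = ["control"] * n_controls + ["patient"] * n_patients
    counters = {"control": 0, "patient": 0}
    for role in roles:
        counters[role] += 1
        sid = f"{role}{counters[role]:02d}"
        child_seed = int(rng.integers(2 ** 31))
        jit = rng.normal(0.0, cc.intensity_jitter_sd, size=3)
        thick = max(base.ribbon_thickness_mm
                    + rng.normal(0.0, cc.thickness_jitter_sd), 0.5)
        lesion = None
        if role == "patient":
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            center_mm = _grid_center_mm(base) + base.wm_radius_mm * direction
            center_vox = tuple(center_mm / np.array(base.spacing))
            lesion = LesionSpec(
                center=center_vox,
                radius_mm=_uniform(rng, cc.lesion_radius_range),
                thickening_factor=_uniform(rng, cc.thickening_factor_range),
                junction_blur_sigma_mm=_uniform(rng, cc.junction_blur_sigma_range),
                wm_hyperintensity_shift=_uniform(rng, cc.wm_shift_range),
            )
        cfg = dataclasses.replace(
            base,
            wm_mean=base.wm_mean + jit[0],
            gm_mean=base.gm_mean + jit[1],
            csf_mean=max(base.csf_mean + jit[2], 1.0),
            ribbon_thickness_mm=thick,
            lesion=lesion,
            seed=child_seed,
            gyral_seed=gyral_seed,
        )
        subjects.append(generate_subject(cfg, subject_id=sid))
    return subjects
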