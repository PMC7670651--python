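"""Seeded synthetic brain-phantom cohorts with ground truth.

The generator emulates the inputs of a volumetric templating study: a cohort
of T1-like brains that share one underlying anatomy, each deformed by a
smooth random diffeomorphic warp plus a small rigid offset, corrupted by a
smooth multiplicative bias field and additive noise, and paired with a
matched integer parcellation.  A 4D generator produces ROI time series with
controllable within-region temporal coherence for regional-homogeneity
validation.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volgrid import (
    AffineTransform,
    LabelMap,
    Volume,
    WarpField,
    apply_transform,
    compose_transforms,
    jacobian_determinant,
)
from .preprocess import SubjectRecord

# canonical label ids used by the phantom parcellation
CSF_ID = 1
VENTRICLE_L_ID = 2
VENTRICLE_R_ID = 3
WM_ID = 10
GM_BASE_ID = 101  # GM parcels are GM_BASE_ID .. GM_BASE_ID + n_parcels - 1

# tissue mean intensities, strictly ordered CSF < GM < WM (T1-like contrast)
CSF_MEAN = 300.0
GM_MEAN = 620.0
WM_MEAN = 1000.0


@dataclass
class PhantomSpec:
    """Study conditions for a synthetic cohort.

    Defaults are the desk-scale conditions used throughout: a 48^3 grid of
    2 mm voxels, 8 subjects, 4 mm peak warps of 12 mm smoothness, small
    rigid jitter, a 0.9-1.1 multiplicative bias field and 3% (of WM) noise.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_mm: float = 2.0
    n_subjects: int = 8
    warp_amplitude_mm: float = 4.0
    warp_smoothness_mm: float = 12.0
    rigid_jitter_deg: float = 3.0
    rigid_jitter_mm: float = 3.0
    bias_range: tuple[float, float] = (0.9, 1.1)
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warp_amplitude_mm < 0 or self.warp_smoothness_mm <= 0:
            raise ValueError("warp amplitude must be >= 0 and smoothness > 0")
        lo, hi = self.bias_range
        if not (lo <= 1.0 <= hi):
            raise ValueError("bias_range must bracket 1.0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def _centered_affine(shape, voxel_mm: float) -> np.ndarray:
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return aff


def make_base_anatomy(
    grid_shape=(48, 48, 48), voxel_mm: float = 2.0, seed: int = 0, n_gm_parcels: int = 16
) -> tuple[Volume, LabelMap]:
    """Build the shared ground-truth anatomy: a nested-ellipsoid brain.

    Background 0, CSF shell, two ventricle lobes, a GM ribbon with
    sinusoidal folds, and a WM core; GM is split into ``n_gm_parcels``
    angular parcels.  A mild smooth intensity texture (deterministic in the
    seed) is layered within tissues so that image registration has contrast
    to work with everywhere, as real parenchyma does.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if min(grid_shape) < 32:
        raise ValueError("grid must be at least 32 voxels per axis")
    if n_gm_parcels < 12:
        raise ValueError("need at least 12 GM parcels")
    rng = np.random.default_rng(seed)
    aff = _centered_affine(grid_shape, voxel_mm)
    idx = np.indices(grid_shape, dtype=np.float64)
    # world coords (grid is axis-aligned)
    x = idx[0] * voxel_mm + aff[0, 3]
    y = idx[1] * voxel_mm + aff[1, 3]
    z = idx[2] * voxel_mm + aff[2, 3]

    fov = np.asarray(grid_shape) * voxel_mm
    # ellipsoid semi-axes (mm); slightly anisotropic like a head
    a_sc = 0.40 * fov[0]
    b_sc = 0.34 * fov[1]
    c_sc = 0.36 * fov[2]
    rho = np.sqrt((x / a_sc) ** 2 + (y / b_sc) ** 2 + (z / c_sc) ** 2)

    theta = np.arctan2(y, x)  # azimuth, for folds and parcels
    phi = np.arctan2(z, np.hypot(x, y))  # elevation

    # sinusoidal cortical folding of the GM/WM boundary
    folds = 0.045 * np.sin(6 * theta) * np.cos(3 * phi) + 0.03 * np.sin(4 * phi)
    gm_inner = 0.68 + folds
    gm_outer = 0.92

    labels = np.zeros(grid_shape, dtype=np.int32)
    labels[rho <= 1.0] = CSF_ID
    gm = (rho <= gm_outer) & (rho > gm_inner)
    wm = rho <= gm_inner
    labels[wm] = WM_ID

    # angular GM parcellation: split azimuth into bands, each band split by
    # hemisphere of elevation, to reach n_gm_parcels regions
    n_theta = int(np.ceil(n_gm_parcels / 2))
    t_bin = np.floor((theta + np.pi) / (2 * np.pi) * n_theta).astype(int)
    t_bin = np.clip(t_bin, 0, n_theta - 1)
    parcel = t_bin * 2 + (phi > 0)
    parcel = np.minimum(parcel, n_gm_parcels - 1)
    labels[gm] = GM_BASE_ID + parcel[gm]

    # two ventricle lobes flanking the midline inside WM
    for vid, sx in ((VENTRICLE_L_ID, -1.0), (VENTRICLE_R_ID, 1.0)):
        vx = (x - sx * 0.12 * fov[0]) / (0.08 * fov[0])
        vy = y / (0.16 * fov[1])
        vz = z / (0.10 * fov[2])
        vent = (vx**2 + vy**2 + vz**2 <= 1.0) & wm
        labels[vent] = vid

    table = {CSF_ID: "CSF", VENTRICLE_L_ID: "Ventricle_L", VENTRICLE_R_ID: "Ventricle_R",
             WM_ID: "WM"}
    for p in range(n_gm_parcels):
        table[GM_BASE_ID + p] = f"GM_parcel_{p + 1:02d}"

    means = np.zeros(grid_shape)
    means[labels == CSF_ID] = CSF_MEAN
    means[(labels == VENTRICLE_L_ID) | (labels == VENTRICLE_R_ID)] = CSF_MEAN
    means[labels >= GM_BASE_ID] = GM_MEAN
    means[labels == WM_ID] = WM_MEAN

    # two-scale within-tissue texture (coarse + fine), as real parenchyma
    # carries structure at many scales; soft edges from a mild blur
    t1 = ndimage.gaussian_filter(rng.standard_normal(grid_shape), sigma=4.0 / voxel_mm)
    t2 = ndimage.gaussian_filter(rng.standard_normal(grid_shape), sigma=2.0 / voxel_mm)
    texture = 0.10 * t1 / max(t1.std(), 1e-12) + 0.12 * t2 / max(t2.std(), 1e-12)
    # white matter is far more homogeneous than cortex on T1; damp its texture
    texture = np.where(labels == WM_ID, 0.35 * texture, texture)
    data = means * np.clip(1.0 + texture, 0.6, 1.4)
    data[labels == 0] = 0.0
    data = ndimage.gaussian_filter(data, sigma=0.6)
    data = np.clip(data, 0.0, None)

    return Volume(data, aff), LabelMap(labels, aff, table)


def random_smooth_warp(
    shape, affine, amplitude_mm: float, smoothness_mm: float, rng: np.random.Generator
) -> WarpField:
    """Random Gaussian-smoothed displacement field with peak ``amplitude_mm``.

    Positive Jacobian is guaranteed by construction: the amplitude is
    rejected up front if it is large relative to the field smoothness, and
    the realised field is additionally clamped if its minimum Jacobian
    determinant approaches zero.
    """
    if amplitude_mm > 0.75 * smoothness_mm:
        raise ValueError(
            f"warp amplitude {amplitude_mm} mm too large for smoothness "
            f"{smoothness_mm} mm; positive Jacobian cannot be guaranteed"
        )
    vox = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
    disp = rng.standard_normal(tuple(shape) + (3,))
    for c in range(3):
        disp[..., c] = ndimage.gaussian_filter(disp[..., c], sigma=smoothness_mm / vox[c])
    mag = np.linalg.norm(disp, axis=-1)
    peak = mag.max()
    if peak > 0 and amplitude_mm > 0:
        disp *= amplitude_mm / peak
    else:
        disp[:] = 0.0
    w = WarpField(disp, np.asarray(affine))
    if amplitude_mm > 0:
        jmin = jacobian_determinant(w).min()
        while jmin <= 0.1:
            disp *= 0.8
            w = WarpField(disp, np.asarray(affine))
            jmin = jacobian_determinant(w).min()
    return w


def _random_rigid(rng: np.random.Generator, max_deg: float, max_mm: float) -> AffineTransform:
    angles = np.deg2rad(rng.uniform(-max_deg, max_deg, 3))
    t = rng.uniform(-max_mm, max_mm, 3)
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    m = np.eye(4)
    m[:3, :3] = rz @ ry @ rx
    m[:3, 3] = t
    return AffineTransform(m)


def _smooth_bias_field(shape, vox, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    f = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(f, sigma=30.0 / np.asarray(vox))
    rng_span = f.max() - f.min()
    if rng_span < 1e-12:
        return np.ones(shape)
    return lo + (f - f.min()) / rng_span * (hi - lo)


def make_cohort(
    spec: PhantomSpec,
) -> list[tuple[SubjectRecord, WarpField, AffineTransform]]:
    """Generate the cohort: per subject a record (image, labels, mask, ICV)
    plus the ground-truth warp field and rigid offset used to create it.

    Each subject image is the base anatomy pulled through rigid-after-warp
    (image-application order: warp first, then the rigid offset); labels are
    pulled identically with nearest-neighbour sampling.  Bias and noise act
    on intensities only.
    """
    rng = np.random.default_rng(spec.seed)
    base_vol, base_lab = make_base_anatomy(spec.grid_shape, spec.voxel_mm, seed=spec.seed)
    aff = base_vol.affine
    shape = base_vol.shape
    vox = base_vol.voxel_sizes
    out = []
    for s in range(spec.n_subjects):
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        warp = random_smooth_warp(shape, aff, spec.warp_amplitude_mm,
                                  spec.warp_smoothness_mm, sub_rng)
        rigid = _random_rigid(sub_rng, spec.rigid_jitter_deg, spec.rigid_jitter_mm)
        total = compose_transforms(warp, rigid, aff, shape)
        # windowed-sinc sampling keeps the phantoms as sharp as real scans
        anat = apply_transform(base_vol, total, aff, shape, method="sinc")
        lab_vol = Volume(base_lab.data.astype(np.float64), base_lab.affine)
        lab_warped = apply_transform(lab_vol, total, aff, shape, method="nearest")
        labels = LabelMap(lab_warped.data.astype(np.int32), aff, dict(base_lab.table))

        bias = _smooth_bias_field(shape, vox, *spec.bias_range, rng=sub_rng)
        data = anat.data * bias
        if spec.noise_sigma > 0:
            data = data + sub_rng.standard_normal(shape) * spec.noise_sigma * WM_MEAN
        data = np.clip(data, 0.0, None)
        anat = Volume(data, aff)

        mask = Volume((labels.data != 0).astype(np.float64), aff)
        icv = float(mask.data.sum() * anat.voxel_volume)
        rec = SubjectRecord(id=f"sub-{s + 1:02d}", anat=anat, labels=labels,
                            mask=mask, icv=icv)
        out.append((rec, warp, rigid))
    return out


def make_bold(
    labels: LabelMap,
    n_timepoints: int = 100,
    coherence_per_roi: dict[int, float] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    default_coherence: float = 0.0,
) -> np.ndarray:
    """4D time-series phantom with controllable within-ROI coherence.

    Every voxel of ROI r gets ``sqrt(c_r) * shared_r(t) +
    sqrt(1 - c_r) * independent(t)`` with unit-variance components, so the
    expected regional homogeneity grows monotonically with c_r.  Optional
    ``noise_sigma`` adds measurement noise on top.
    """
    coherence_per_roi = dict(coherence_per_roi or {})
    present = set(labels.ids())
    unknown = set(coherence_per_roi) - present
    if unknown:
        raise ValueError(f"coherence map names ROI ids absent from labels: {sorted(unknown)}")
    for rid, c in coherence_per_roi.items():
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"coherence for ROI {rid} outside [0, 1]: {c}")
    rng = np.random.default_rng(seed)
    shape = labels.shape
    bold = rng.standard_normal(shape + (n_timepoints,))
    for rid in sorted(present):
        c = coherence_per_roi.get(rid, default_coherence)
        if c <= 0:
            continue
        shared = rng.standard_normal(n_timepoints)
        m = labels.data == rid
        bold[m] = np.sqrt(c) * shared + np.sqrt(1.0 - c) * bold[m]
    if noise_sigma > 0:
        bold = bold + noise_sigma * rng.standard_normal(bold.shape)
    bold[labels.data == labels.background_id] = 0.0
    return bold
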