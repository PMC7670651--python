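"""Per-subject preparation: intensity unification, label-derived brain
masks, and rigid "axialization" onto a reference grid.

Axialization fits a full affine but applies only its rigid part, so subject
brains are re-oriented into a common isotropic space without any change of
shape or size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .volgrid import (
    AffineTransform,
    LabelMap,
    Volume,
    apply_transform,
)


@dataclass
class SubjectRecord:
    """One subject's prepared inputs.

    ``icv`` is the intracranial volume in mm^3, defined as brain-mask voxel
    count times voxel volume.
    """

    id: str
    anat: Volume
    labels: LabelMap | None = None
    mask: Volume | None = None
    icv: float | None = None

    def __post_init__(self) -> None:
        if self.mask is not None:
            vals = np.unique(self.mask.data)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError(f"subject {self.id}: mask must be binary 0/1")
            if self.icv is None:
                self.icv = float(self.mask.data.sum() * self.mask.voxel_volume)


# --------------------------------------------------------------------------
# intensity unification
# --------------------------------------------------------------------------

def _block_median_field(intens: np.ndarray, sel: np.ndarray, block_vox: int,
                        sigma_vox: float) -> np.ndarray:
    """Smooth bias surrogate: per-block median of selected (bright) voxels,
    Gaussian-smoothed and upsampled back to the full grid."""
    shape = intens.shape
    nb = [max(1, int(np.ceil(s / block_vox))) for s in shape]
    med = np.full(nb, np.nan)
    for i in range(nb[0]):
        for j in range(nb[1]):
            for k in range(nb[2]):
                sl = tuple(
                    slice(c * block_vox, min((c + 1) * block_vox, s))
                    for c, s in zip((i, j, k), shape)
                )
                vals = intens[sl][sel[sl]]
                if vals.size >= 4:
                    med[i, j, k] = np.median(vals)
    valid = np.isfinite(med)
    if not valid.any():
        med = np.ones_like(med)
    elif not valid.all():
        # extend the field from the nearest sampled block, so gradients are
        # not flattened by a constant fill
        _, idxs = ndimage.distance_transform_edt(~valid, return_indices=True)
        med = med[tuple(idxs)]
    med = ndimage.gaussian_filter(med, sigma=sigma_vox / block_vox)
    zoom = [s / n for s, n in zip(shape, nb)]
    field = ndimage.zoom(med, zoom, order=1, grid_mode=True, mode="nearest")
    return field[: shape[0], : shape[1], : shape[2]]


def _bright_threshold(vals: np.ndarray) -> float:
    """Two-cluster 1D k-means split of an intensity sample; returns the
    midpoint between the cluster centres (the bright-tissue cut)."""
    v = np.asarray(vals, dtype=np.float64)
    v = v[v > 0]
    if v.size < 10 or np.ptp(v) < 1e-9:
        raise ValueError("cannot split a (near-)constant intensity distribution")
    lo, hi = np.percentile(v, [10, 90])
    c = np.array([lo, hi], dtype=np.float64)
    for _ in range(50):
        assign = np.abs(v[:, None] - c[None, :]).argmin(axis=1)
        newc = np.array([v[assign == k].mean() if np.any(assign == k) else c[k]
                         for k in range(2)])
        if np.allclose(newc, c, rtol=1e-6):
            break
        c = newc
    return float(c.mean())


def _upper_mode(vals: np.ndarray) -> float:
    """Intensity mode of the brighter of two intensity populations.

    A two-cluster 1D k-means splits the histogram; the mode of the upper
    cluster is located by kernel density estimation.
    """
    v = np.asarray(vals, dtype=np.float64)
    v = v[v > 0]
    if v.size < 10 or np.ptp(v) < 1e-9:
        raise ValueError("cannot locate an intensity mode on (near-)constant data")
    upper = v[v > _bright_threshold(v)]
    if upper.size < 10:
        upper = v
    if np.ptp(upper) < 1e-9:
        return float(upper[0])
    sample = upper if upper.size <= 20000 else np.random.default_rng(0).choice(
        upper, 20000, replace=False)
    kde = stats.gaussian_kde(sample)
    grid = np.linspace(upper.min(), upper.max(), 256)
    return float(grid[np.argmax(kde(grid))])


def unify_intensity(
    vol: Volume, mask: Volume, wm_target: float = 1000.0, sigma_mm: float = 25.0
) -> Volume:
    """Divide out a smooth multiplicative bias field and rescale so the
    white-matter intensity mode lands at ``wm_target``.

    The bias field is estimated from the local median of bright tissue
    (above the in-mask median), smoothed at ``sigma_mm``; WM is taken as the
    upper mode of the two-population intensity histogram inside the mask.
    """
    m = mask.data > 0.5
    if not np.any(m):
        raise ValueError("empty mask")
    inside = vol.data[m]
    if np.ptp(inside) < 1e-9:
        raise ValueError("image is constant inside the mask")
    if inside.min() < -1e-9:
        raise ValueError("expected a nonnegative image")
    vox = float(np.mean(vol.voxel_sizes))
    bright = m & (vol.data > _bright_threshold(inside))
    block = max(2, int(round(sigma_mm / 2.0 / vox)))
    field = _block_median_field(vol.data, bright, block, sigma_mm / vox)
    field = np.clip(field, 1e-6, None)
    field /= field[m].mean()
    corrected = vol.data / field
    mode = _upper_mode(corrected[m])
    out = np.clip(corrected * (wm_target / mode), 0.0, None)
    return Volume(out, vol.affine.copy())


# --------------------------------------------------------------------------
# label-derived brain mask
# --------------------------------------------------------------------------

def mask_from_labels(labels: LabelMap, dilate: int = 3, erode: int = 2) -> Volume:
    """Union of all non-background labels, dilated then eroded (morphological
    closing with a face-connected structuring element); interior holes are
    filled while dilated so they cannot reopen."""
    union = labels.data != labels.background_id
    if not np.any(union):
        raise ValueError("all-background label map")
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connected
    m = union
    if dilate > 0:
        m = ndimage.binary_dilation(m, structure=struct, iterations=dilate)
    m = ndimage.binary_fill_holes(m)
    if erode > 0:
        m = ndimage.binary_erosion(m, structure=struct, iterations=erode)
    return Volume(m.astype(np.float64), labels.affine.copy())


# --------------------------------------------------------------------------
# axialization
# --------------------------------------------------------------------------

def axialize(
    vol: Volume,
    reference: Volume,
    weight: Volume | None = None,
    cost: str = "lpa",
    seed: int = 0,
) -> tuple[Volume, AffineTransform]:
    """Rigidly re-orient ``vol`` into the reference space.

    A full 12-parameter affine is fitted, its rigid (rotation+translation)
    part extracted, and only that applied; the output is resampled onto the
    reference grid with windowed-sinc interpolation, so shape and size are
    untouched up to interpolation.
    """
    from .register import affine_register, rigid_from_affine

    ref_vox = reference.voxel_sizes
    if not np.allclose(ref_vox, ref_vox[0], rtol=1e-3):
        raise ValueError("reference grid must be isotropic")
    full = affine_register(vol, reference, dof=12, cost=cost, weight=weight, seed=seed)
    rigid = rigid_from_affine(full)
    out = apply_transform(vol, rigid, reference.affine, reference.shape, method="sinc")
    return out, rigid
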