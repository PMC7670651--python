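"""Maximum-probability-map (MPM) atlases and modally smoothed typical-
subject atlases in template space.

Subject parcellations are carried into template space with nearest-
neighbour sampling (so region identity is preserved), then fused by
per-voxel vote: each region's vote fraction is its probability of mapping
to that voxel, the winning region forms the atlas, and the winner's
fraction is stored as the max-probability map.  All fractions are exact
rationals (integer counts over n subjects).
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
)

_NEIGHBORHOODS = {"faces-7": 1, "edges-19": 2, "full-27": 3}


def neighborhood_footprint(neighborhood: str) -> np.ndarray:
    """3x3x3 boolean footprint (centre included) for a named neighbourhood."""
    try:
        conn = _NEIGHBORHOODS[neighborhood]
    except KeyError:
        raise ValueError(f"unknown neighborhood: {neighborhood!r}") from None
    return ndimage.generate_binary_structure(3, conn)


@dataclass
class MPMAtlas:
    labels: LabelMap
    maxprob: Volume
    prob_maps: dict[int, np.ndarray] = field(repr=False)
    n_subjects: int = 0


def warp_labels(
    labels: LabelMap,
    total_warp: WarpField | AffineTransform | None,
    target_affine,
    target_shape,
) -> LabelMap:
    """Carry a parcellation through a transform with nearest-neighbour
    sampling; no new label ids can appear and the table is carried over."""
    vol = Volume(labels.data.astype(np.float64), labels.affine)
    out = apply_transform(vol, total_warp, target_affine, target_shape, method="nearest")
    return LabelMap(out.data.astype(np.int32), out.affine, dict(labels.table),
                    labels.background_id)


def build_mpm(
    warped_labels: list[LabelMap],
    background_policy: str = "background-competes",
) -> MPMAtlas:
    """Fuse warped parcellations into an MPM atlas by per-voxel vote.

    Winner is the region with the most votes (ties to the smallest id).
    Under ``background-competes`` (default) a voxel is background when
    background holds a strict plurality over every region — otherwise
    cohort-edge voxels would inherit labels from single outlier subjects;
    ``background-excluded`` labels any voxel where at least one region
    voted.
    """
    if background_policy not in ("background-competes", "background-excluded"):
        raise ValueError(f"unknown background policy: {background_policy!r}")
    if len(warped_labels) < 2:
        raise ValueError("need at least 2 label maps")
    first = warped_labels[0]
    table: dict[int, str] = {}
    for lm in warped_labels:
        if lm.shape != first.shape or not np.allclose(lm.affine, first.affine, atol=1e-6):
            raise ValueError("label maps must share a grid")
        for k, v in lm.table.items():
            if k in table and table[k] != v:
                raise ValueError(f"conflicting names for label {k}: {table[k]!r} vs {v!r}")
            table[k] = v
    n = len(warped_labels)
    bg = first.background_id
    ids = sorted({int(i) for lm in warped_labels for i in np.unique(lm.data)} - {bg})

    counts = np.zeros((len(ids),) + first.shape, dtype=np.int16)
    for lm in warped_labels:
        for j, rid in enumerate(ids):
            counts[j] += lm.data == rid
    roi_total = counts.sum(axis=0)
    bg_count = n - roi_total

    if ids:
        best_j = counts.argmax(axis=0)  # ties -> first (smallest id)
        best_c = np.take_along_axis(counts, best_j[None], axis=0)[0]
    else:
        best_j = np.zeros(first.shape, dtype=int)
        best_c = np.zeros(first.shape, dtype=np.int16)

    id_arr = np.asarray(ids, dtype=np.int32) if ids else np.asarray([bg])
    win = id_arr[best_j]
    if background_policy == "background-competes":
        is_bg = bg_count > best_c  # strict plurality for background
    else:
        is_bg = best_c == 0
    win = np.where(is_bg, bg, win)
    maxprob = np.where(is_bg, 0.0, best_c / n)

    prob_maps = {rid: counts[j] / n for j, rid in enumerate(ids)}
    labels = LabelMap(win.astype(np.int32), first.affine.copy(), table, bg)
    return MPMAtlas(labels=labels, maxprob=Volume(maxprob, first.affine.copy()),
                    prob_maps=prob_maps, n_subjects=n)


def modal_smooth(
    labels: LabelMap, neighborhood: str = "faces-7", iters: int = 1
) -> LabelMap:
    """Replace each voxel with the modal label of its neighbourhood (centre
    included).  Ties keep the current value when it is among the modes,
    otherwise the smallest label id wins; the value set never grows."""
    fp = neighborhood_footprint(neighborhood).astype(np.int32)
    data = labels.data.copy()
    for _ in range(max(0, iters)):
        vals = np.unique(data)
        counts = np.stack([
            ndimage.correlate((data == v).astype(np.int32), fp, mode="constant", cval=0)
            for v in vals
        ])
        best = counts.max(axis=0)
        is_mode = counts == best[None]
        cur_idx = np.searchsorted(vals, data)
        keep = np.take_along_axis(is_mode, cur_idx[None], axis=0)[0]
        smallest_mode = vals[is_mode.argmax(axis=0)]  # first True -> smallest id
        new = np.where(keep, data, smallest_mode)
        if np.array_equal(new, data):
            break
        data = new
    return LabelMap(data, labels.affine.copy(), dict(labels.table), labels.background_id)


def build_typical_atlas(
    subject_labels: LabelMap,
    subject_to_template: WarpField | AffineTransform | None,
    target_affine,
    target_shape,
) -> LabelMap:
    """Typical-subject atlas: warp the parcellation to template space
    (nearest neighbour) and lightly regularize with one facewise modal
    smoothing pass."""
    warped = warp_labels(subject_labels, subject_to_template, target_affine, target_shape)
    return modal_smooth(warped, neighborhood="faces-7", iters=1)
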