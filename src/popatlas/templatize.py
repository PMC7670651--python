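"""Iterative align-and-average template construction.

The driver alternates between aligning every cohort member to the current
reference base and averaging the aligned brains into a new base, at
increasing refinement: one rigid stage, one full-affine stage with an
intracranial-volume (ICV) rescale so the template keeps a cohort-
representative size, then a ladder of nonlinear stages at decreasing
minimum patch sizes.  Per stage it records the cohort mean, the cohort
standard-deviation map, every subject's running total transform, and the
grey/white contrast-to-noise ratio; stage means are edge-preserving
smoothed before serving as the next base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import SubjectRecord
from .register import (
    RegistrationConfig,
    affine_register,
    cost_lpa,
    nonlinear_register,
    rigid_from_affine,
)
from .volgrid import (
    AffineTransform,
    Volume,
    WarpField,
    affine_to_warp,
    apply_transform,
    compose_transforms,
    invert_warp,
)


# --------------------------------------------------------------------------
# schedule
# --------------------------------------------------------------------------

@dataclass
class StageEntry:
    name: str
    kind: str  # rigid | affine | nonlinear
    patch_mm: float = 0.0
    blur_base_mm: float = 0.0
    blur_source_mm: float = 0.0
    source_filter: str = "gaussian"


@dataclass
class StageSchedule:
    stages: list[StageEntry]

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("schedule needs at least rigid + affine stages")
        if self.stages[0].kind != "rigid" or self.stages[1].kind != "affine":
            raise ValueError("first stage must be rigid, second affine")
        patches = [s.patch_mm for s in self.stages if s.kind == "nonlinear"]
        if patches != sorted(patches, reverse=True) or len(set(patches)) != len(patches):
            raise ValueError("nonlinear patch sizes must be strictly decreasing")


def default_schedule() -> StageSchedule:
    """The standard five-stage nonlinear ladder following rigid and affine:
    minimum patch sizes 101/49/23/13/9 mm with base/source blurs
    0/9, 1/6, 0/4, 0/2(median), 0/2(median) mm."""
    return StageSchedule([
        StageEntry("rigid", "rigid"),
        StageEntry("affine", "affine"),
        StageEntry("NL0", "nonlinear", 101.0, 0.0, 9.0, "gaussian"),
        StageEntry("NL1", "nonlinear", 49.0, 1.0, 6.0, "gaussian"),
        StageEntry("NL2", "nonlinear", 23.0, 0.0, 4.0, "gaussian"),
        StageEntry("NL3", "nonlinear", 13.0, 0.0, 2.0, "median"),
        StageEntry("NL4", "nonlinear", 9.0, 0.0, 2.0, "median"),
    ])


def schedule_from_dict(entries) -> StageSchedule:
    return StageSchedule([StageEntry(**e) for e in entries])


# --------------------------------------------------------------------------
# stage results
# --------------------------------------------------------------------------

@dataclass
class TemplateStageResult:
    stage_name: str
    mean: Volume
    sd: Volume
    per_subject_transforms: list
    cnr: float
    mask: Volume | None = None  # fused (majority-vote) warped subject masks
    mean_sd: float = float("nan")  # mean of the SD map inside `mask`


@dataclass
class TemplateBundle:
    template: Volume
    stages: list[TemplateStageResult]
    v_coh: float
    total_warps: list[WarpField]
    subject_ids: list[str]
    typical_subject_id: str
    mask: Volume | None = None  # final-stage fused brain mask
    typical_ranking: pd.DataFrame = field(repr=False, default=None)


# --------------------------------------------------------------------------
# primitive operations
# --------------------------------------------------------------------------

def average_aligned(volumes: list[Volume]) -> tuple[Volume, Volume]:
    """Voxelwise mean and population standard deviation (divisor N)."""
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes")
    first = volumes[0]
    for v in volumes[1:]:
        if not first.same_grid(v):
            raise ValueError("volumes must share a grid")
    stack = np.stack([v.data for v in volumes])
    return (
        Volume(stack.mean(axis=0), first.affine.copy()),
        Volume(stack.std(axis=0, ddof=0), first.affine.copy()),
    )


def rescale_to_cohort_icv(
    mean_vol: Volume, mean_mask: Volume, v_coh: float, method: str = "sinc"
) -> tuple[Volume, float, AffineTransform]:
    """Isotropically rescale a mean volume about its mask's centre of mass so
    the brain-mask volume matches the cohort-mean ICV.

    Returns the rescaled volume, the per-axis length factor
    (v_coh / V_mask)^(1/3), and the applied pull-affine (so masks and
    transforms can be rescaled consistently).
    """
    if v_coh <= 0:
        raise ValueError("v_coh must be positive")
    m = mean_mask.data > 0.5
    if not np.any(m):
        raise ValueError("empty mean mask")
    v_aff = float(m.sum() * mean_mask.voxel_volume)
    r_vol = v_coh / v_aff
    factor = r_vol ** (1.0 / 3.0)
    ijk = np.argwhere(m).mean(axis=0)
    com = mean_vol.affine[:3, :3] @ ijk + mean_vol.affine[:3, 3]
    # pull map: x -> com + (x - com) / factor  (scales content by `factor`)
    mtx = np.eye(4)
    mtx[:3, :3] = np.eye(3) / factor
    mtx[:3, 3] = com - com / factor
    xf = AffineTransform(mtx)
    out = apply_transform(mean_vol, xf, mean_vol.affine, mean_vol.shape, method=method)
    return out, float(factor), xf


def sharpen_edges(vol: Volume, iters: int = 10, conductance: float = 50.0) -> Volume:
    """Edge-preserving (Perona-Malik) anisotropic diffusion.

    Written in flux-divergence form with zero-flux boundaries, so the global
    mean is conserved exactly; ``conductance`` is the intensity-gradient
    scale (per voxel) below which smoothing acts and above which edges are
    preserved.
    """
    if iters < 0:
        raise ValueError("iters must be >= 0")
    u = vol.data.copy()
    dt = 1.0 / 7.0
    k2 = float(conductance) ** 2
    for _ in range(iters):
        upd = np.zeros_like(u)
        for ax in range(3):
            d = np.diff(u, axis=ax)
            g = 1.0 / (1.0 + d * d / k2)
            flux = g * d
            pad = [(0, 0)] * 3
            pad[ax] = (1, 1)
            flux = np.pad(flux, pad)  # zero flux at the boundary
            upd += np.diff(flux, axis=ax)
        u = u + dt * upd
    return Volume(u, vol.affine.copy())


def compute_cnr(vol: Volume, gm_mask: Volume | np.ndarray, wm_mask: Volume | np.ndarray) -> float:
    """GM/WM contrast-to-noise ratio:
    |mean(WM) - mean(GM)| / sqrt((var(GM) + var(WM)) / 2)."""
    gm = (gm_mask.data if isinstance(gm_mask, Volume) else np.asarray(gm_mask)) > 0.5
    wm = (wm_mask.data if isinstance(wm_mask, Volume) else np.asarray(wm_mask)) > 0.5
    if not np.any(gm) or not np.any(wm):
        raise ValueError("empty tissue mask")
    if np.any(gm & wm):
        raise ValueError("tissue masks overlap")
    g = vol.data[gm]
    w = vol.data[wm]
    denom = np.sqrt((g.var() + w.var()) / 2.0)
    if denom < 1e-12:
        return 0.0
    return float(abs(w.mean() - g.mean()) / denom)


def select_typical(
    cohort_aligned: list[tuple[str, Volume]], template: Volume, patch_mm: float = 24.0
) -> tuple[str, pd.DataFrame]:
    """Pick the cohort member most similar to the template by the local
    Pearson cost; ties break lexicographically by id."""
    if not cohort_aligned:
        raise ValueError("empty cohort")
    rows = []
    for sid, vol in cohort_aligned:
        mask = (template.data > 0.05 * template.data.max()) | (vol.data > 0.05 * vol.data.max())
        c = cost_lpa(vol, template, patch_mm, mask=mask)
        rows.append({"id": sid, "lpa_cost": c})
    tbl = pd.DataFrame(rows).sort_values(["lpa_cost", "id"], kind="mergesort")
    tbl = tbl.reset_index(drop=True)
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    return str(tbl.iloc[0]["id"]), tbl


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

def _tissue_ids(table: dict[int, str]) -> tuple[list[int], list[int]]:
    gm = [i for i, n in table.items() if n.upper().startswith("GM")]
    wm = [i for i, n in table.items() if "WM" in n.upper() or "WHITE" in n.upper()]
    return gm, wm


def _warp_mask(rec: SubjectRecord, total, aff, shape) -> np.ndarray:
    mv = apply_transform(rec.mask, total, aff, shape, method="linear")
    return mv.data


def serial_map(fn, items):
    """Order-preserving serial map (the default parallel_map contract)."""
    return [fn(x) for x in items]


def build_template(
    cohort: list[SubjectRecord],
    schedule: StageSchedule | None = None,
    reference: Volume | None = None,
    parallel_map=serial_map,
    seed: int = 0,
    sharpen_iters: int = 2,
    sharpen_conductance: float = 30.0,
    nl_max_iters: int = 80,
    nl_rel_tol: float = 0.03,  # stage converged once steps gain < 3% cost
    gm_ids: list[int] | None = None,
    wm_ids: list[int] | None = None,
    recenter: bool = True,
    progress=None,
) -> TemplateBundle:
    """Run the full align-and-average ladder over a preprocessed cohort.

    ``reference`` seeds the rigid stage (defaults to the first subject's
    image); ``parallel_map`` must be an order-preserving map.  Returns the
    final template, per-stage results, and each subject's total transform as
    a dense warp on the template grid.
    """
    if len(cohort) < 3:
        raise ValueError("need at least 3 subjects")
    schedule = schedule or default_schedule()
    if reference is None:
        reference = cohort[0].anat
    aff = reference.affine
    shape = reference.shape

    for rec in cohort:
        if rec.mask is None:
            raise ValueError(f"subject {rec.id}: missing brain mask")
    v_coh = float(np.mean([rec.icv for rec in cohort]))

    # tissue ids for CNR tracking
    if gm_ids is None or wm_ids is None:
        for rec in cohort:
            if rec.labels is not None and rec.labels.table:
                g, w = _tissue_ids(rec.labels.table)
                gm_ids = gm_ids or g
                wm_ids = wm_ids or w
                break
    totals: list[AffineTransform | WarpField] = [AffineTransform.identity()] * len(cohort)
    stages: list[TemplateStageResult] = []
    base = reference

    for si, stage in enumerate(schedule.stages):
        if progress:
            progress(f"stage {stage.name}")

        def align_one(item, _stage=stage, _base=base):
            idx, rec = item
            try:
                if _stage.kind == "rigid":
                    full = affine_register(rec.anat, _base, dof=12, cost="lpa", seed=seed)
                    return rigid_from_affine(full)
                if _stage.kind == "affine":
                    # start from the rigid-aligned image, fold into total
                    src = apply_transform(rec.anat, totals[idx], aff, shape, "linear")
                    inc = affine_register(src, _base, dof=12, cost="lpa", seed=seed)
                    return compose_transforms(inc, totals[idx])
                cfg = RegistrationConfig(
                    cost="pcl",
                    patch_mm=_stage.patch_mm,
                    blur_base_mm=_stage.blur_base_mm,
                    blur_source_mm=_stage.blur_source_mm,
                    source_filter=_stage.source_filter,
                    max_iters=nl_max_iters,
                    step_mm=float(np.min(rec.anat.voxel_sizes)),
                    rel_tol=nl_rel_tol,
                    seed=seed,
                )
                # register the subject as currently aligned; the pure stage
                # increment comes back so the driver can recentre it
                src_stage = apply_transform(rec.anat, totals[idx], aff, shape, "linear")
                return nonlinear_register(src_stage, _base, cfg, init=None)
            except Exception as e:  # noqa: BLE001 - reported with subject id
                raise RuntimeError(f"subject {rec.id} failed at stage {_stage.name}: {e}") from e

        results = list(parallel_map(align_one, list(enumerate(cohort))))

        if stage.kind == "nonlinear":
            incs = results
            if recenter:
                # unbiased-template correction: subtract the cohort-mean
                # stage increment from every subject's increment so the
                # template cannot drift collectively (first-order centering;
                # stage increments are small, so this is essentially exact)
                mean_disp = np.mean([w.displacements for w in incs], axis=0)
                incs = [WarpField(w.displacements - mean_disp, aff) for w in incs]
            totals = [compose_transforms(e, t) for e, t in zip(incs, totals)]
        else:
            totals = results

        # high-order sinc resampling for the averages, to minimize smoothing
        aligned = [
            apply_transform(rec.anat, t, aff, shape, "sinc")
            for rec, t in zip(cohort, totals)
        ]
        mean, sd = average_aligned(aligned)

        # cohort-size control: rescale the mean so its mask volume matches
        # the cohort-mean ICV, and fold the rescale into every total
        mask_mean = np.mean(
            [_warp_mask(rec, t, aff, shape) for rec, t in zip(cohort, totals)], axis=0
        )
        mean_mask = Volume((mask_mean > 0.5).astype(float), aff)
        mean, factor, resc = rescale_to_cohort_icv(mean, mean_mask, v_coh)
        sd = apply_transform(sd, resc, aff, shape, "linear")
        totals = [compose_transforms(resc, t, aff, shape) for t in totals]

        if stage.kind == "nonlinear":
            # the first nonlinear mean is the blurriest; smooth it more
            # lightly so what little detail it has survives, and let the
            # finer later means take the full smoothing
            first_nl = stage.name == next(s.name for s in schedule.stages
                                          if s.kind == "nonlinear")
            iters = max(1, sharpen_iters - 1) if first_nl else sharpen_iters
            mean = sharpen_edges(mean, iters=iters, conductance=sharpen_conductance)

        fused = np.mean(
            [_warp_mask(rec, t, aff, shape) for rec, t in zip(cohort, totals)], axis=0
        )
        fused_mask = Volume((fused > 0.5).astype(float), aff)
        mean_sd = float(sd.data[fused_mask.data > 0.5].mean())
        stages.append(TemplateStageResult(stage.name, mean, sd, list(totals), float("nan"),
                                          mask=fused_mask, mean_sd=mean_sd))
        base = mean

    # CNR per stage, measured on the stage products in one consistent pair
    # of tissue masks (the final stage's majority-vote GM/WM), so the
    # trajectory reflects the template's contrast rather than shifting mask
    # definitions
    gm_mask, wm_mask = _voted_tissue_masks(cohort, stages[-1].per_subject_transforms,
                                           aff, shape, gm_ids, wm_ids)
    if gm_mask is not None:
        for st in stages:
            st.cnr = compute_cnr(st.mean, gm_mask, wm_mask)

    template = stages[-1].mean
    total_warps = [
        t if isinstance(t, WarpField) else affine_to_warp(t, aff, shape) for t in totals
    ]
    aligned_final = [
        (rec.id, apply_transform(rec.anat, t, aff, shape, "linear"))
        for rec, t in zip(cohort, totals)
    ]
    typical_id, ranking = select_typical(aligned_final, template)
    return TemplateBundle(
        template=template,
        stages=stages,
        v_coh=v_coh,
        total_warps=total_warps,
        subject_ids=[rec.id for rec in cohort],
        typical_subject_id=typical_id,
        mask=stages[-1].mask,
        typical_ranking=ranking,
    )


def _voted_tissue_masks(cohort, totals, aff, shape, gm_ids, wm_ids):
    """Majority-vote GM and WM masks in template space (boundary voxels
    included: interface sharpening is part of the contrast signal)."""
    if not gm_ids or not wm_ids:
        return None, None
    gm_votes = np.zeros(shape)
    wm_votes = np.zeros(shape)
    n = 0
    for rec, t in zip(cohort, totals):
        if rec.labels is None:
            continue
        lab = apply_transform(
            Volume(rec.labels.data.astype(float), rec.labels.affine), t, aff, shape, "nearest"
        ).data.astype(int)
        gm_votes += np.isin(lab, gm_ids)
        wm_votes += np.isin(lab, wm_ids)
        n += 1
    if n == 0:
        return None, None
    gm = gm_votes > n / 2.0
    wm = (wm_votes > n / 2.0) & ~gm
    if not gm.any() or not wm.any():
        return None, None
    return gm.astype(float), wm.astype(float)


def template_mask(template: Volume, level: float = 0.12) -> Volume:
    """Brain mask of a template by thresholding at ``level`` x the robust
    (99.5th percentile) maximum, keeping the largest connected component and
    filling holes."""
    thr = level * np.percentile(template.data, 99.5)
    m = template.data > thr
    lab, n = ndimage.label(m)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        m = lab == (1 + int(np.argmax(sizes)))
    m = ndimage.binary_fill_holes(m)
    return Volume(m.astype(float), template.affine.copy())
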