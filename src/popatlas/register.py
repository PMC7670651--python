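"""Intra-contrast image registration: local-Pearson and clipped-Pearson
costs, affine fitting with rigid extraction, and multi-resolution nonlinear
registration.

The nonlinear optimizer drives a dense displacement field through gradient
descent on the (global) Pearson cost, with each update restricted to a
control grid of spacing ``patch_mm / 2`` and Gaussian-smoothed at
``patch_mm / 4`` — "minimum patch size" is the finest spatial scale a stage
is allowed to refine.  A backtracking line search keeps the configured cost
strictly non-increasing over accepted iterations and rejects steps that
would fold the deformation (positive-Jacobian fraction below 99.5%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .volgrid import (
    AffineTransform,
    Volume,
    WarpField,
    apply_transform,
    compose_transforms,
    grid_world_coords,
    jacobian_determinant,
    world_to_voxel,
)


@dataclass
class RegistrationConfig:
    """Parameters of one nonlinear stage."""

    cost: str = "pcl"
    patch_mm: float = 24.0
    blur_base_mm: float = 0.0
    blur_source_mm: float = 0.0
    source_filter: str = "gaussian"
    max_iters: int = 100
    step_mm: float = 1.0
    elastic_vox: float = 0.7  # total-field smoothing inside each trial step
    rel_tol: float = 0.002  # minimum relative cost decrease per accepted step
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.patch_mm <= 0:
            raise ValueError("patch_mm must be positive")
        if self.blur_base_mm < 0 or self.blur_source_mm < 0:
            raise ValueError("blur values must be nonnegative")
        if self.cost not in ("lpa", "pcl"):
            raise ValueError(f"unknown cost: {self.cost!r}")
        if self.source_filter not in ("gaussian", "median"):
            raise ValueError(f"unknown source filter: {self.source_filter!r}")


# --------------------------------------------------------------------------
# cost functions
# --------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom < 1e-12:
        raise ValueError("constant input to Pearson correlation")
    return float((ac @ bc) / denom)


def cost_lpa(
    a: Volume | np.ndarray,
    b: Volume | np.ndarray,
    patch_mm: float,
    mask: np.ndarray | Volume | None = None,
    voxel_sizes=None,
) -> float:
    """Mean absolute local Pearson cost: 1 - mean |r| over overlapping cubic
    patches of side ``patch_mm`` (50% overlap); lower is better, range [0,1].

    Patches with (near-)zero variance in either image, or with fewer than 8
    in-mask voxels, are excluded; if none survive an error is raised.
    """
    ad, bd, vox, m = _as_arrays(a, b, mask, voxel_sizes)
    side = [int(np.clip(round(patch_mm / v), 2, s)) for v, s in zip(vox, ad.shape)]
    steps = [max(1, s // 2) for s in side]
    rs = []
    for ox in _origins(ad.shape[0], side[0], steps[0]):
        for oy in _origins(ad.shape[1], side[1], steps[1]):
            for oz in _origins(ad.shape[2], side[2], steps[2]):
                sl = (slice(ox, ox + side[0]), slice(oy, oy + side[1]),
                      slice(oz, oz + side[2]))
                pm = m[sl]
                if pm.sum() < 8:
                    continue
                av = ad[sl][pm]
                bv = bd[sl][pm]
                if av.std() < 1e-10 or bv.std() < 1e-10:
                    continue
                rs.append(abs(_pearson(av, bv)))
    if not rs:
        raise ValueError("no valid patch for the local Pearson cost")
    return float(1.0 - np.mean(rs))


def _origins(dim: int, side: int, step: int) -> list[int]:
    out = list(range(0, max(dim - side, 0) + 1, step))
    if out[-1] != dim - side and dim - side > 0:
        out.append(dim - side)
    return out


def cost_pcl(
    a: Volume | np.ndarray,
    b: Volume | np.ndarray,
    clip_q: float = 0.02,
    mask: np.ndarray | Volume | None = None,
) -> float:
    """Clipped (winsorized) Pearson cost: 1 - r after per-image winsorization
    at quantiles (clip_q, 1-clip_q); range [0, 2], lower is better."""
    ad, bd, _, m = _as_arrays(a, b, mask, None)
    av, bv = ad[m], bd[m]
    av = _winsorize(av, clip_q)
    bv = _winsorize(bv, clip_q)
    if av.std() < 1e-12 or bv.std() < 1e-12:
        raise ValueError("image constant after clipping")
    return float(1.0 - _pearson(av, bv))


def _winsorize(v: np.ndarray, q: float) -> np.ndarray:
    if q <= 0:
        return v
    lo, hi = np.quantile(v, [q, 1.0 - q])
    return np.clip(v, lo, hi)


def _as_arrays(a, b, mask, voxel_sizes):
    if isinstance(a, Volume):
        voxel_sizes = a.voxel_sizes
        ad = a.data
    else:
        ad = np.asarray(a, dtype=np.float64)
    bd = b.data if isinstance(b, Volume) else np.asarray(b, dtype=np.float64)
    if ad.shape != bd.shape:
        raise ValueError("inputs must share a grid")
    if isinstance(a, Volume) and isinstance(b, Volume):
        if not np.allclose(a.affine, b.affine, atol=1e-6):
            raise ValueError("inputs must share a grid")
    if mask is None:
        m = np.ones(ad.shape, dtype=bool)
    else:
        md = mask.data if isinstance(mask, Volume) else np.asarray(mask)
        m = md > 0.5
    if voxel_sizes is None:
        voxel_sizes = np.ones(3)
    return ad, bd, np.asarray(voxel_sizes, dtype=float), m


def evaluate_cost(cfg_cost: str, a, b, patch_mm: float, mask=None, voxel_sizes=None) -> float:
    if cfg_cost == "lpa":
        return cost_lpa(a, b, patch_mm, mask=mask, voxel_sizes=voxel_sizes)
    return cost_pcl(a, b, mask=mask)


# --------------------------------------------------------------------------
# affine registration
# --------------------------------------------------------------------------

def _params_to_matrix(p: np.ndarray, center: np.ndarray, dof: int) -> np.ndarray:
    """(tx,ty,tz, rx,ry,rz[deg] [, log-scales*100, shears*100]) -> 4x4 about
    ``center``."""
    t = p[:3]
    ang = np.deg2rad(p[3:6])
    cx, cy, cz = np.cos(ang)
    sx, sy, sz = np.sin(ang)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    lin = rz @ ry @ rx
    if dof == 12:
        scales = np.exp(p[6:9] / 100.0)
        h = p[9:12] / 100.0
        sh = np.array([[1, h[0], h[1]], [0, 1, h[2]], [0, 0, 1]])
        lin = lin @ sh @ np.diag(scales)
    m = np.eye(4)
    m[:3, :3] = lin
    m[:3, 3] = t + center - lin @ center
    return m


def _downsample2(data: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = ndimage.gaussian_filter(data, sigma=1.0)[::2, ::2, ::2]
    aff = affine.copy()
    aff[:3, :3] *= 2.0
    return d, aff


def affine_register(
    source: Volume,
    base: Volume,
    dof: int = 12,
    cost: str = "lpa",
    weight: Volume | None = None,
    patch_mm: float | None = None,
    seed: int = 0,
    blur_mm: float = 2.0,
) -> AffineTransform:
    """Fit a world-space affine (pull convention: maps base-space points to
    source-space points) minimizing the chosen cost.

    Multi-resolution: a deterministic multi-start over coarse rotations
    feeds a Powell search on a downsampled pyramid (6 rigid parameters
    first, then scales/shears for dof=12), with a final polish at full
    resolution.  Raises if the optimum fails to improve on the identity.
    """
    if dof not in (6, 12):
        raise ValueError("dof must be 6 or 12")
    vox_b = base.voxel_sizes
    bd = ndimage.gaussian_filter(base.data, sigma=blur_mm / vox_b) if blur_mm > 0 else base.data
    sd = (
        ndimage.gaussian_filter(source.data, sigma=blur_mm / source.voxel_sizes)
        if blur_mm > 0
        else source.data
    )
    thr = 0.05 * np.percentile(bd, 99.5)
    mask0 = bd > thr
    if weight is not None:
        mask0 &= weight.data > 0
    mask0 = ndimage.binary_dilation(mask0, iterations=2)
    if not np.any(mask0):
        raise ValueError("empty registration mask")
    if patch_mm is None:
        patch_mm = float(np.min(np.asarray(base.shape) * vox_b) / 2.0)
    center = grid_world_coords(base.affine, base.shape)[:, mask0.ravel()].mean(axis=1)

    # crop to the mask bounding box (+margin) to cut resampling cost
    bb = ndimage.find_objects(mask0.astype(np.int8))[0]
    bb = tuple(slice(max(0, s.start - 2), min(n, s.stop + 2))
               for s, n in zip(bb, base.shape))
    bd_c = np.ascontiguousarray(bd[bb])
    mask_c = mask0[bb]
    aff_c = base.affine.copy()
    aff_c[:3, 3] += base.affine[:3, :3] @ np.array([s.start for s in bb], dtype=float)

    # resolution pyramid (coarsest first)
    levels = [(bd_c, aff_c, sd, source.affine.copy(), mask_c)]
    while min(levels[0][0].shape) >= 24:
        cb, cba = _downsample2(levels[0][0], levels[0][1])
        cs, csa = _downsample2(levels[0][2], levels[0][3])
        cm = levels[0][4][::2, ::2, ::2]
        if min(cb.shape) < 12 or not cm.any():
            break
        levels.insert(0, (cb, cba, cs, csa, cm))

    def make_cost(level):
        lbd, lba, lsd, lsa, lm = level
        pts = grid_world_coords(lba, lbd.shape)
        inv_src = np.linalg.inv(lsa)
        lvox = np.linalg.norm(lba[:3, :3], axis=0)

        def cost_of(p: np.ndarray, d: int) -> float:
            mtx = _params_to_matrix(p, center, d)
            sp = mtx[:3, :3] @ pts + mtx[:3, 3:4]
            coords = inv_src[:3, :3] @ sp + inv_src[:3, 3:4]
            w = ndimage.map_coordinates(lsd, coords, order=1, mode="constant",
                                        cval=0.0).reshape(lbd.shape)
            try:
                return evaluate_cost(cost, w, lbd, patch_mm, mask=lm, voxel_sizes=lvox)
            except ValueError:
                return 2.0

        return cost_of

    coarse_cost = make_cost(levels[0])
    # deterministic multi-start over coarse rotations
    starts = [np.zeros(6)]
    for ax in range(3):
        for sgn in (-1.0, 1.0):
            p = np.zeros(6)
            p[3 + ax] = 12.0 * sgn
            starts.append(p)
    p0 = starts[int(np.argmin([coarse_cost(p, 6) for p in starts]))]

    p = p0
    for li, level in enumerate(levels):
        cost_of = make_cost(level)
        finest = li == len(levels) - 1
        opts = {"xtol": 1e-3 if finest else 5e-3,
                "ftol": 1e-7 if finest else 1e-6,
                "maxfev": 500 if finest else 900}
        if not (finest and dof == 12):  # finest pass refines 12-dof directly
            res6 = optimize.minimize(cost_of, p[:6], args=(6,), method="Powell",
                                     options=opts)
            p = np.asarray(res6.x)
        if dof == 12:
            p12 = np.concatenate([p, np.zeros(6)]) if p.size == 6 else p
            res12 = optimize.minimize(cost_of, p12, args=(12,), method="Powell",
                                      options=opts)
            p = np.asarray(res12.x)

    fine_cost = make_cost(levels[-1])
    best_dof = dof
    best_p = p if p.size == (12 if dof == 12 else 6) else np.concatenate([p, np.zeros(6)])
    best_c = fine_cost(best_p, best_dof)
    c_ident = fine_cost(np.zeros(best_p.size), best_dof)
    if best_c > c_ident + 1e-9:
        raise RuntimeError(
            f"affine registration failed to improve on identity "
            f"(cost {best_c:.6f} vs {c_ident:.6f})"
        )
    return AffineTransform(_params_to_matrix(best_p, center, best_dof))


def rigid_from_affine(xf: AffineTransform) -> AffineTransform:
    """Rotation-only part of an affine via polar decomposition; translation
    is preserved, scales and shears removed.  Reflections are rejected."""
    lin = xf.matrix[:3, :3]
    if np.linalg.det(lin) <= 0:
        raise ValueError("affine contains a reflection (negative determinant)")
    u, _, vt = np.linalg.svd(lin)
    rot = u @ vt
    if np.linalg.det(rot) < 0:  # guard: flip smallest singular direction
        u[:, -1] *= -1
        rot = u @ vt
    m = np.eye(4)
    m[:3, :3] = rot
    m[:3, 3] = xf.matrix[:3, 3]
    return AffineTransform(m)


# --------------------------------------------------------------------------
# nonlinear registration
# --------------------------------------------------------------------------

def _blur_source(data: np.ndarray, cfg: RegistrationConfig, vox: np.ndarray) -> np.ndarray:
    if cfg.blur_source_mm <= 0:
        return data
    if cfg.source_filter == "median":
        # window must span the stated width: odd size, >= 3 when any
        # filtering is requested (a 1-voxel window would be a no-op)
        size = [2 * int(np.ceil(cfg.blur_source_mm / (2 * v))) + 1 for v in vox]
        return ndimage.median_filter(data, size=size)
    return ndimage.gaussian_filter(data, sigma=cfg.blur_source_mm / vox)


def _control_project(field: np.ndarray, spacing_vox: np.ndarray) -> np.ndarray:
    """Restrict a dense per-axis field to a coarse control grid and
    prolongate back (linear), band-limiting the update to the control
    spacing."""
    shape = np.asarray(field.shape)
    nctrl = np.maximum(2, np.ceil(shape / spacing_vox).astype(int) + 1)
    if np.all(nctrl >= shape):
        return field
    coarse = ndimage.zoom(field, nctrl / shape, order=1, grid_mode=True, mode="nearest")
    fine = ndimage.zoom(coarse, shape / np.asarray(coarse.shape), order=1,
                        grid_mode=True, mode="nearest")
    return fine[: shape[0], : shape[1], : shape[2]]


def nonlinear_register(
    source: Volume,
    base: Volume,
    cfg: RegistrationConfig,
    init: AffineTransform | WarpField | None = None,
    mask: Volume | None = None,
) -> WarpField:
    """Estimate a dense warp (pull convention, world mm) aligning ``source``
    to ``base`` on the base grid; ``init`` is composed into the result.

    See the module docstring for the optimization scheme.
    """
    shape = base.shape
    aff = base.affine
    vox = base.voxel_sizes
    bd = base.data
    if cfg.blur_base_mm > 0:
        bd = ndimage.gaussian_filter(bd, sigma=cfg.blur_base_mm / vox)
    src_pre = Volume(_blur_source(source.data, cfg, source.voxel_sizes), source.affine)
    # match effective resolution: top up the sharper image so the demons
    # force compares like with like (an asymmetric blur would bias edges)
    extra = cfg.blur_source_mm**2 - cfg.blur_base_mm**2
    if extra > 0:
        bd = ndimage.gaussian_filter(bd, sigma=np.sqrt(extra) / vox)
    elif extra < 0:
        src_pre = Volume(
            ndimage.gaussian_filter(src_pre.data, sigma=np.sqrt(-extra) / source.voxel_sizes),
            src_pre.affine,
        )
    # one resampling of the (pre-filtered) source through init
    src_w = apply_transform(src_pre, init, aff, shape, method="linear")

    if mask is not None:
        m_full = mask.data > 0.5
    else:
        thr = 0.05 * np.percentile(bd, 99.5)
        m_full = (bd > thr) | (src_w.data > thr)
    if not np.any(m_full):
        raise ValueError("empty registration mask")

    # optimize inside the mask bounding box (+margin); outside stays zero
    bb = ndimage.find_objects(m_full.astype(np.int8))[0]
    bb = tuple(slice(max(0, s.start - 4), min(n, s.stop + 4))
               for s, n in zip(bb, shape))
    cshape = tuple(s.stop - s.start for s in bb)
    caff = aff.copy()
    caff[:3, 3] += aff[:3, :3] @ np.array([s.start for s in bb], dtype=float)
    bd_c = np.ascontiguousarray(bd[bb])
    src_c = np.ascontiguousarray(src_w.data[bb])
    m = m_full[bb]

    patch_vox = np.asarray([cfg.patch_mm / v for v in vox])
    ctrl_vox = np.clip(patch_vox / 2.0, 1.5, np.asarray(cshape) / 2.0)
    sigma_vox = np.clip(patch_vox / 4.0, 0.75, None)

    pts = grid_world_coords(caff, cshape)
    # src_w lives on the full grid; sample it in full-grid voxel coords
    src_grid_aff = aff

    def sample(u_arr: np.ndarray) -> np.ndarray:
        coords = world_to_voxel(src_grid_aff, pts + u_arr.reshape(-1, 3).T)
        return ndimage.map_coordinates(src_w.data, coords, order=1, mode="constant",
                                       cval=0.0).reshape(cshape)

    def total_cost(img: np.ndarray) -> float:
        return evaluate_cost(cfg.cost, img, bd_c, cfg.patch_mm, mask=m, voxel_sizes=vox)

    def jac_ok(u_arr: np.ndarray) -> bool:
        frac = float(np.mean(jacobian_determinant(WarpField(u_arr, caff))[m] > 0))
        return frac >= 0.995

    u = np.zeros(cshape + (3,))
    warped = sample(u)
    try:
        cur = total_cost(warped)
    except ValueError as e:
        raise ValueError(f"cost undefined at start: {e}") from e
    if not np.isfinite(cur):
        raise ValueError("non-finite cost")

    step = cfg.step_mm
    min_step = 0.02 * float(vox.min())
    bvals = bd_c[m]
    bc = bvals - bvals.mean()
    bnorm = float(np.sqrt(bc @ bc))
    last_good = u.copy()
    accepts = 0

    b_sd = float(bvals.std())
    b_mean = float(bvals.mean())
    if b_sd < 1e-12:
        raise ValueError("constant base image inside the mask")
    bn = (bd_c - b_mean) / b_sd  # unit-variance base for the demons force

    for _ in range(cfg.max_iters):
        a = warped[m]
        a_sd = float(a.std())
        if a_sd < 1e-12 or bnorm < 1e-12:
            break
        an = (warped - float(a.mean())) / a_sd
        # demons-style force on variance-normalized intensities: bounded,
        # locally scaled displacement estimate in mm; symmetric (ESM)
        # gradient of the mean image stabilizes convergence
        diff = np.where(m, an - bn, 0.0)
        gx, gy, gz = np.gradient(0.5 * (an + bn), *vox)
        g2 = gx * gx + gy * gy + gz * gz
        denom = g2 + diff * diff
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(denom > 1e-9, diff / denom, 0.0)
        force = np.stack([scale * gx, scale * gy, scale * gz], axis=-1)
        for c in range(3):
            force[..., c] = ndimage.gaussian_filter(force[..., c], sigma=sigma_vox)
            force[..., c] = _control_project(force[..., c], ctrl_vox)
        fmag = np.linalg.norm(force, axis=-1)
        fscale = float(np.percentile(fmag[m], 98))
        if fscale < 1e-16:
            break
        np.clip(force / fscale, -2.0, 2.0, out=force)

        accepted = False
        while step >= min_step:
            u_try = u - step * force
            if cfg.elastic_vox > 0:
                for c in range(3):
                    u_try[..., c] = ndimage.gaussian_filter(u_try[..., c],
                                                            cfg.elastic_vox)
            warped_try = sample(u_try)
            try:
                c_try = total_cost(warped_try)
            except ValueError:
                c_try = np.inf
            if np.isfinite(c_try) and c_try < cur - max(1e-10, cfg.rel_tol * cur):
                # fold-free check amortized: every 4th accept and on big steps
                check = (accepts % 4 == 0) or (step > vox.min())
                if not check or jac_ok(u_try):
                    if check:
                        last_good = u_try.copy()
                    u, warped, cur = u_try, warped_try, c_try
                    accepts += 1
                    accepted = True
                    step = min(step * 1.25, 4.0 * cfg.step_mm)
                    break
            step *= 0.5
        if not accepted:
            break
    if cfg.verbose:
        print(f"[nonlinear patch={cfg.patch_mm}] accepts={accepts} cost={cur:.5f}")

    if not jac_ok(u):  # final guarantee: fall back to last verified field
        u = last_good
    u_full = np.zeros(shape + (3,))
    u_full[bb] = u
    inc = WarpField(u_full, aff)
    if init is None:
        return inc
    out = compose_transforms(inc, init)
    assert isinstance(out, WarpField)
    return out


def multiscale_nonlinear_register(
    source: Volume,
    base: Volume,
    patch_schedule_mm,
    cost: str = "pcl",
    init: AffineTransform | WarpField | None = None,
    mask: Volume | None = None,
    max_iters: int = 100,
    step_mm: float | None = None,
) -> WarpField:
    """Run nonlinear stages at successively smaller minimum patch sizes,
    composing each increment into the running total."""
    total = init
    for patch in patch_schedule_mm:
        cfg = RegistrationConfig(
            cost=cost, patch_mm=float(patch), max_iters=max_iters,
            step_mm=step_mm if step_mm is not None else float(base.voxel_sizes.min()),
        )
        total = nonlinear_register(source, base, cfg, init=total, mask=mask)
    assert isinstance(total, WarpField)
    return total


def ncc(a: Volume | np.ndarray, b: Volume | np.ndarray,
        mask: np.ndarray | Volume | None = None) -> float:
    """Normalized cross-correlation (global Pearson r) between two images."""
    ad, bd, _, m = _as_arrays(a, b, mask, None)
    return _pearson(ad[m], bd[m])
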