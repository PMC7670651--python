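"""Validation statistics for templates and atlases.

Covers: the log relative volume ratio of MPM regions against cohort-mean
fractional volumes; the region-wise mean deformation value (L1 norm of the
warp, averaged over a region); axis-wise median absolute displacement with
the paired Wilcoxon signed-rank test; and regional homogeneity (ReHo,
Kendall's coefficient of concordance W) with paired t-tests across
template spaces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .atlas import MPMAtlas, neighborhood_footprint
from .volgrid import LabelMap, Volume, WarpField


# --------------------------------------------------------------------------
# volume representativeness (log relative volume ratio)
# --------------------------------------------------------------------------

def relative_volume_ratio(
    mpm: MPMAtlas | LabelMap,
    template_icv: float,
    subject_tables: pd.DataFrame,
) -> pd.DataFrame:
    """Per-region log relative volume ratio

        r_i = ln[ (V_MPM,i / V_MPM,ICV) / mean_j(V_j,i / V_j,ICV) ]

    comparing each region's fractional volume in the MPM atlas with the
    cohort-mean fractional volume in native space.  Values near 0 mean the
    atlas region is representative; negative/positive values mean relative
    compression/expansion.  ``subject_tables`` needs columns
    ``subject, roi, volume_mm3, icv_mm3``.  Regions absent from the MPM are
    reported with r_i = NaN and flagged undefined.
    """
    labels = mpm.labels if isinstance(mpm, MPMAtlas) else mpm
    if template_icv <= 0:
        raise ValueError("template ICV must be positive")
    req = {"subject", "roi", "volume_mm3", "icv_mm3"}
    if not req <= set(subject_tables.columns):
        raise ValueError(f"subject table needs columns {sorted(req)}")
    if (subject_tables["icv_mm3"] <= 0).any():
        raise ValueError("all subject ICVs must be positive")
    vv = labels.voxel_volume
    mpm_ids = set(labels.ids())
    rows = []
    frac = subject_tables.assign(
        frac=subject_tables["volume_mm3"] / subject_tables["icv_mm3"]
    )
    n_subj = frac["subject"].nunique()
    for rid, grp in frac.groupby("roi"):
        # cohort mean over all subjects (absent regions count as volume 0)
        mean_frac = grp["frac"].sum() / n_subj
        in_mpm = int(rid) in mpm_ids
        v_i = float(np.count_nonzero(labels.data == rid) * vv)
        mpm_frac = v_i / template_icv
        if not in_mpm or mean_frac <= 0:
            rows.append({"roi": int(rid), "mpm_frac": mpm_frac,
                         "cohort_mean_frac": mean_frac, "r": np.nan,
                         "defined": False})
            continue
        rows.append({"roi": int(rid), "mpm_frac": mpm_frac,
                     "cohort_mean_frac": mean_frac,
                     "r": float(np.log(mpm_frac / mean_frac)), "defined": True})
    return pd.DataFrame(rows).set_index("roi").sort_index()


# --------------------------------------------------------------------------
# deformation statistics
# --------------------------------------------------------------------------

def mean_deformation_value(warp: WarpField, roi_mask: Volume | np.ndarray) -> float:
    """Mean over region voxels of |dx| + |dy| + |dz| (mm): a proxy for how
    much deformation the region needed, hence intersubject variability."""
    m = (roi_mask.data if isinstance(roi_mask, Volume) else np.asarray(roi_mask)) > 0.5
    if m.shape != warp.shape:
        raise ValueError("mask grid does not match the warp grid")
    if not np.any(m):
        raise ValueError("empty ROI")
    return float(np.abs(warp.displacements[m]).sum(axis=-1).mean())


def median_axis_displacement(
    warp: WarpField, brain_mask: Volume | np.ndarray
) -> tuple[float, float, float]:
    """Median absolute displacement per world axis (LR, PA, IS) in mm."""
    m = (brain_mask.data if isinstance(brain_mask, Volume) else np.asarray(brain_mask)) > 0.5
    if m.shape != warp.shape:
        raise ValueError("mask grid does not match the warp grid")
    if not np.any(m):
        raise ValueError("empty mask")
    med = np.median(np.abs(warp.displacements[m]), axis=0)
    return float(med[0]), float(med[1]), float(med[2])


# --------------------------------------------------------------------------
# Wilcoxon signed-rank test
# --------------------------------------------------------------------------

def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """PMF (unnormalised counts) of the positive-rank sum over all 2^n sign
    assignments, by polynomial convolution over doubled (integer) ranks."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1, dtype=np.float64)
    dist[0] = 1.0
    for r in ranks2:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    return dist


def wilcoxon_signed_rank(
    paired_a, paired_b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped; tied magnitudes get mid-ranks.  The null
    distribution is exact (all 2^n sign patterns, via convolution) for
    n <= 25 and a continuity-corrected normal approximation with tie
    correction above.  Returns (W+ statistic, p).
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    if d.size < 5:
        raise ValueError("need at least 5 nonzero paired differences")
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        r2 = np.rint(2 * ranks).astype(int)
        dist = _signed_rank_distribution(r2)
        total = 2.0**n
        w2 = int(round(2 * w_plus))
        p_le = dist[: w2 + 1].sum() / total
        p_ge = dist[w2:].sum() / total
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        sd = np.sqrt(var)
        p_ge = stats.norm.sf((w_plus - 0.5 - mean) / sd)
        p_le = stats.norm.cdf((w_plus + 0.5 - mean) / sd)
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return w_plus, float(p)


def compare_axis_displacements(
    warps_a: list[tuple[float, float, float]],
    warps_b: list[tuple[float, float, float]],
    alternative: str = "two-sided",
    bonferroni_n: int = 15,
) -> pd.DataFrame:
    """Paired Wilcoxon tests of per-subject axis-wise median displacements
    between two template spaces, Bonferroni-corrected (default factor 15 =
    3 axes x 5 cohorts)."""
    a = np.asarray(warps_a, dtype=float)
    b = np.asarray(warps_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("need matching (n, 3) axis-median arrays")
    rows = []
    for ax, name in enumerate(("LR", "PA", "IS")):
        w, p = wilcoxon_signed_rank(a[:, ax], b[:, ax], alternative=alternative)
        rows.append({
            "axis": name,
            "median_a": float(np.median(a[:, ax])),
            "median_b": float(np.median(b[:, ax])),
            "statistic": w,
            "p": p,
            "p_corrected": min(1.0, p * bonferroni_n),
            "significant_corrected": p * bonferroni_n < 0.05,
        })
    return pd.DataFrame(rows).set_index("axis")


# --------------------------------------------------------------------------
# regional homogeneity (Kendall's W)
# --------------------------------------------------------------------------

def reho_kendall_w(series: np.ndarray, tie_correction: bool = False) -> float:
    """Kendall's coefficient of concordance W over m series of n timepoints.

    W = 12 sum_t (R_t - m(n+1)/2)^2 / (m^2 n (n^2 - 1)) with R_t the column
    sum of within-series ranks (mid-ranks for ties).  1 = perfectly
    concordant rankings, 0 = no concordance.  By default no tie correction
    is applied; ``tie_correction=True`` subtracts the classical tie term
    from the denominator.
    """
    s = np.asarray(series, dtype=np.float64)
    if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] < 2:
        raise ValueError("need an (m >= 2, n >= 2) series matrix")
    m, n = s.shape
    for i in range(m):
        if np.ptp(s[i]) == 0:
            raise ValueError(f"series {i} is constant; ranks undefined")
    ranks = np.apply_along_axis(stats.rankdata, 1, s)
    r_t = ranks.sum(axis=0)
    ssd = float(((r_t - m * (n + 1) / 2.0) ** 2).sum())
    denom = m * m * n * (n * n - 1) / 12.0
    if tie_correction:
        tie = 0.0
        for i in range(m):
            _, cnt = np.unique(ranks[i], return_counts=True)
            tie += float((cnt**3 - cnt).sum())
        denom -= m * tie / 12.0
    if denom <= 0:
        return 0.0
    return float(min(1.0, ssd / denom))


def voxelwise_reho(
    bold: np.ndarray,
    mask: Volume | np.ndarray,
    neighborhood: str = "full-27",
) -> np.ndarray:
    """Per-voxel ReHo: Kendall's W over the time series of the voxel and its
    in-mask neighbours.  Voxels with fewer than 2 in-mask neighbours get 0.

    Vectorised via neighbourhood sums of the per-voxel temporal ranks; this
    matches :func:`reho_kendall_w` applied voxel by voxel (no tie
    correction).
    """
    bold = np.asarray(bold, dtype=np.float64)
    if bold.ndim != 4:
        raise ValueError("bold must be 4D (x, y, z, t)")
    n = bold.shape[3]
    if n < 10:
        raise ValueError("need at least 10 timepoints")
    m = (mask.data if isinstance(mask, Volume) else np.asarray(mask)) > 0.5
    if m.shape != bold.shape[:3]:
        raise ValueError("mask grid does not match the bold grid")
    fp = neighborhood_footprint(neighborhood).astype(np.float64)

    ranks = np.zeros_like(bold)
    ranks[m] = stats.rankdata(bold[m], axis=1)  # mid-ranks over time

    mcount = ndimage.correlate(m.astype(np.float64), fp, mode="constant", cval=0.0)
    mcount[~m] = 0.0
    s = np.zeros(bold.shape[:3] + (n,))
    for t in range(n):
        s[..., t] = ndimage.correlate(ranks[..., t], fp, mode="constant", cval=0.0)
    ssd = ((s - mcount[..., None] * (n + 1) / 2.0) ** 2).sum(axis=-1)
    denom = mcount**2 * n * (n * n - 1) / 12.0
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, ssd / denom, 0.0)
    w = np.clip(w, 0.0, 1.0)
    w[~m] = 0.0
    w[mcount < 3] = 0.0  # voxel + at least 2 in-mask neighbours
    return w


def roi_reho_compare(
    bold_a: list[np.ndarray],
    bold_b: list[np.ndarray],
    atlas_a: LabelMap,
    atlas_b: LabelMap,
    correction: str = "bonferroni",
    neighborhood: str = "full-27",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-tests of per-subject mean ROI ReHo between two spaces.

    For each subject the voxelwise ReHo map is averaged within every atlas
    region; regions are then compared across subjects A vs B.  Bonferroni
    correction divides alpha by the number of regions tested.
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction: {correction!r}")
    if len(bold_a) != len(bold_b) or len(bold_a) < 2:
        raise ValueError("need the same subjects (>= 2) in both spaces")
    ids_a, ids_b = set(atlas_a.ids()), set(atlas_b.ids())
    if ids_a != ids_b:
        raise ValueError(
            f"ROI id sets differ: only in A {sorted(ids_a - ids_b)}, "
            f"only in B {sorted(ids_b - ids_a)}"
        )
    ids = sorted(ids_a)

    def roi_means(bold_list, atl):
        mask = atl.data != atl.background_id
        out = np.zeros((len(bold_list), len(ids)))
        for si, bold in enumerate(bold_list):
            w = voxelwise_reho(bold, mask.astype(float), neighborhood=neighborhood)
            for ri, rid in enumerate(ids):
                sel = atl.data == rid
                out[si, ri] = w[sel].mean() if sel.any() else np.nan
        return out

    ma = roi_means(bold_a, atlas_a)
    mb = roi_means(bold_b, atlas_b)
    n_tests = len(ids)
    rows = []
    for ri, rid in enumerate(ids):
        diff = ma[:, ri] - mb[:, ri]
        if np.allclose(diff, 0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_rel(ma[:, ri], mb[:, ri])
        p_corr = min(1.0, p * n_tests) if correction == "bonferroni" else p
        rows.append({
            "roi": rid,
            "reho_a": float(ma[:, ri].mean()),
            "reho_b": float(mb[:, ri].mean()),
            "mean_diff": float(diff.mean()),
            "t": float(t_stat),
            "p": float(p),
            "p_corrected": float(p_corr),
            "significant_raw": bool(p < alpha),
            "significant_corrected": bool(p_corr < alpha),
        })
    return pd.DataFrame(rows).set_index("roi")
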