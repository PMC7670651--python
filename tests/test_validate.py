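"""Validation statistics: relative volume ratio, deformation measures,
Wilcoxon signed-rank, and regional homogeneity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from popatlas import (
    LabelMap,
    Volume,
    WarpField,
    mean_deformation_value,
    median_axis_displacement,
    reho_kendall_w,
    relative_volume_ratio,
    roi_reho_compare,
    voxelwise_reho,
    wilcoxon_signed_rank,
)
from popatlas.atlas import MPMAtlas


# --------------------------------------------------------------------------
# relative volume ratio
# --------------------------------------------------------------------------

def _mpm_with_fraction(frac, icv_vox=1000, shape=(12, 12, 12)):
    data = np.zeros(shape, np.int32)
    n_roi = int(round(frac * icv_vox))
    data.ravel()[:n_roi] = 1
    return MPMAtlas(LabelMap(data, np.eye(4), {1: "roi"}),
                    Volume(np.zeros(shape), np.eye(4)), {}, 2)


def _subject_table(frac, n=4, icv=1000.0):
    return pd.DataFrame([
        {"subject": f"s{j}", "roi": 1, "volume_mm3": frac * icv, "icv_mm3": icv}
        for j in range(n)
    ])


class TestRelativeVolumeRatio:
    @pytest.mark.parametrize("mpm_frac, cohort_frac, expect", [
        (0.02, 0.02, 0.0),
        (0.04, 0.02, np.log(2.0)),
        (0.01, 0.02, -np.log(2.0)),
    ])
    def test_hand_cases(self, mpm_frac, cohort_frac, expect):
        mpm = _mpm_with_fraction(mpm_frac)
        out = relative_volume_ratio(mpm, 1000.0, _subject_table(cohort_frac))
        assert out.loc[1, "r"] == pytest.approx(expect, abs=1e-12)

    def test_round_trip_identity_random_tables(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            mpm_frac = rng.uniform(0.005, 0.2)
            mpm = _mpm_with_fraction(mpm_frac)
            rows = []
            for j in range(5):
                icv = rng.uniform(800, 1500)
                rows.append({"subject": f"s{j}", "roi": 1,
                             "volume_mm3": rng.uniform(0.005, 0.2) * icv,
                             "icv_mm3": icv})
            tbl = pd.DataFrame(rows)
            out = relative_volume_ratio(mpm, 1000.0, tbl)
            cohort_mean = (tbl["volume_mm3"] / tbl["icv_mm3"]).mean()
            recovered = np.exp(out.loc[1, "r"]) * cohort_mean
            assert recovered == pytest.approx(out.loc[1, "mpm_frac"], abs=1e-12)

    def test_missing_roi_flagged_undefined(self):
        mpm = _mpm_with_fraction(0.02)
        tbl = pd.concat([_subject_table(0.02),
                         _subject_table(0.01).assign(roi=9)])
        out = relative_volume_ratio(mpm, 1000.0, tbl)
        assert not out.loc[9, "defined"]
        assert np.isnan(out.loc[9, "r"])


# --------------------------------------------------------------------------
# deformation statistics
# --------------------------------------------------------------------------

class TestDeformationStats:
    def test_constant_displacement_closed_form(self):
        disp = np.zeros((6, 6, 6, 3))
        disp[...] = (1.0, 2.0, 2.0)
        w = WarpField(disp, np.eye(4))
        mask = np.ones((6, 6, 6))
        assert mean_deformation_value(w, mask) == pytest.approx(5.0, abs=1e-12)
        assert median_axis_displacement(w, mask) == pytest.approx((1.0, 2.0, 2.0))

    def test_zero_warp(self):
        w = WarpField.zeros((5, 5, 5), np.eye(4))
        mask = np.ones((5, 5, 5))
        assert mean_deformation_value(w, mask) == 0.0
        assert median_axis_displacement(w, mask) == (0.0, 0.0, 0.0)

    def test_matches_brute_force_on_random_fields(self):
        rng = np.random.default_rng(21)
        disp = rng.normal(0, 2, (7, 7, 7, 3))
        w = WarpField(disp, np.eye(4))
        mask = rng.random((7, 7, 7)) > 0.6
        got = mean_deformation_value(w, mask.astype(float))
        expect = np.mean([np.abs(disp[tuple(i)]).sum() for i in np.argwhere(mask)])
        assert got == pytest.approx(expect, abs=1e-12)
        med = median_axis_displacement(w, mask.astype(float))
        for ax in range(3):
            assert med[ax] == pytest.approx(
                np.median(np.abs(disp[mask][:, ax])), abs=1e-12)

    def test_empty_roi_errors(self):
        w = WarpField.zeros((4, 4, 4), np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            mean_deformation_value(w, np.zeros((4, 4, 4)))


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------

def wilcoxon_enumeration(d, alternative):
    """Exact p by looping over all 2^n sign assignments (oracle)."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ge = le = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    total = 2.0**n
    if alternative == "greater":
        return w_obs, ge / total
    if alternative == "less":
        return w_obs, le / total
    return w_obs, min(1.0, 2 * min(ge / total, le / total))


class TestWilcoxon:
    def test_all_positive_n5_two_sided(self):
        stat, p = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
        assert p == pytest.approx(2 / 32, abs=1e-12)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])

    def test_one_sided_matches_enumeration(self):
        a = np.array([1, 2, 3, 4, 5, -6], float)
        b = np.zeros(6)
        _, p = wilcoxon_signed_rank(a, b, alternative="greater")
        _, p_oracle = wilcoxon_enumeration(a - b, "greater")
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            d = rng.normal(0.3, 1.0, 10)
            d = d[d != 0]
            stat, p = wilcoxon_signed_rank(d, np.zeros_like(d))
            res = stats.wilcoxon(d, alternative="two-sided", mode="exact")
            assert p == pytest.approx(res.pvalue, abs=1e-10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 10),
           st.sampled_from(["two-sided", "greater", "less"]))
    def test_enumeration_property_with_ties(self, seed, n, alternative):
        rng = np.random.default_rng(seed)
        # quantized values force tied magnitudes and mid-ranks
        d = np.round(rng.normal(0, 2, n) * 2) / 2
        d = d[d != 0]
        if d.size < 5:
            return
        got_stat, got_p = wilcoxon_signed_rank(d, np.zeros_like(d), alternative)
        exp_stat, exp_p = wilcoxon_enumeration(d, alternative)
        assert got_stat == pytest.approx(exp_stat, abs=1e-9)
        assert got_p == pytest.approx(exp_p, abs=1e-9)

    def test_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(23)
        d = rng.normal(0.5, 1.0, 40)
        _, p = wilcoxon_signed_rank(d, np.zeros_like(d))
        res = stats.wilcoxon(d, alternative="two-sided", mode="approx",
                             correction=True)
        assert p == pytest.approx(res.pvalue, rel=0.05)


# --------------------------------------------------------------------------
# ReHo / Kendall's W
# --------------------------------------------------------------------------

class TestKendallW:
    def test_identical_series_give_one(self):
        base = np.sin(np.linspace(0, 4, 20))
        series = np.tile(base, (5, 1))
        assert reho_kendall_w(series) == pytest.approx(1.0, abs=1e-12)

    def test_rank_reversal_gives_zero(self):
        a = np.arange(10.0)
        series = np.stack([a, a[::-1]])
        assert reho_kendall_w(series) == pytest.approx(0.0, abs=1e-12)

    def test_hand_built_ranks_match_formula(self):
        series = np.array([
            [1.0, 4.0, 2.0, 3.0],
            [2.0, 3.0, 1.0, 4.0],
            [1.0, 2.0, 3.0, 4.0],
        ])
        m, n = series.shape
        ranks = np.array([stats.rankdata(s) for s in series])
        r_t = ranks.sum(axis=0)
        expect = ((r_t - m * (n + 1) / 2) ** 2).sum() * 12 / (m * m * n * (n * n - 1))
        assert reho_kendall_w(series) == pytest.approx(expect, abs=1e-12)

    def test_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(24)
        series = rng.normal(0, 1, (4, 15))
        w0 = reho_kendall_w(series)
        transformed = np.stack([
            np.exp(series[0]), 3 * series[1] + 2, series[2] ** 3, np.arctan(series[3]),
        ])
        assert reho_kendall_w(transformed) == pytest.approx(w0, abs=1e-12)

    def test_constant_series_error_names_index(self):
        series = np.random.default_rng(0).normal(0, 1, (3, 8))
        series[1] = 5.0
        with pytest.raises(ValueError, match="series 1"):
            reho_kendall_w(series)


class TestVoxelwiseReho:
    def test_shared_sinusoid_gives_one_inside(self):
        t = np.sin(np.linspace(0, 12, 40))
        bold = np.broadcast_to(t, (8, 8, 8, 40)).copy()
        mask = np.ones((8, 8, 8))
        w = voxelwise_reho(bold, mask)
        np.testing.assert_allclose(w[2:-2, 2:-2, 2:-2], 1.0, atol=1e-10)

    def test_white_noise_is_low(self):
        rng = np.random.default_rng(25)
        vals = []
        for seed in (1, 2, 3):
            bold = np.random.default_rng(seed).standard_normal((8, 8, 8, 100))
            mask = np.ones((8, 8, 8))
            vals.append(voxelwise_reho(bold, mask).mean())
        assert np.mean(vals) < 0.15

    def test_matches_direct_kendall_w_per_voxel(self):
        rng = np.random.default_rng(26)
        bold = rng.standard_normal((5, 5, 5, 12))
        mask = rng.random((5, 5, 5)) > 0.3
        w = voxelwise_reho(bold, mask.astype(float), neighborhood="faces-7")
        from popatlas.atlas import neighborhood_footprint

        fp = neighborhood_footprint("faces-7")
        offs = np.argwhere(fp) - 1
        for idx in np.argwhere(mask):
            members = []
            for o in offs:
                j = idx + o
                if np.all(j >= 0) and np.all(j < 5) and mask[tuple(j)]:
                    members.append(bold[tuple(j)])
            if len(members) < 3:
                assert w[tuple(idx)] == 0.0
            else:
                expect = reho_kendall_w(np.asarray(members))
                assert w[tuple(idx)] == pytest.approx(expect, abs=1e-10)

    def test_too_few_timepoints_error(self):
        with pytest.raises(ValueError, match="timepoints"):
            voxelwise_reho(np.zeros((4, 4, 4, 5)), np.ones((4, 4, 4)))


class TestRoiRehoCompare:
    def _labels(self):
        data = np.zeros((8, 8, 8), np.int32)
        data[:4, :4] = 1
        data[4:, :4] = 2
        data[:4, 4:] = 3
        data[4:, 4:] = 4
        return LabelMap(data, np.eye(4), {i: f"r{i}" for i in range(1, 5)})

    def test_identical_spaces_not_significant(self):
        from popatlas.synthgen import make_bold

        labels = self._labels()
        bolds = [make_bold(labels, 30, {1: 0.5, 2: 0.5, 3: 0.5, 4: 0.5}, seed=s)
                 for s in range(3)]
        out = roi_reho_compare(bolds, [b.copy() for b in bolds], labels, labels)
        assert np.allclose(out["mean_diff"], 0.0)
        assert not out["significant_corrected"].any()

    def test_higher_coherence_space_wins(self):
        from popatlas.synthgen import make_bold

        labels = self._labels()
        coher_hi = {i: 0.7 for i in range(1, 5)}
        coher_lo = {i: 0.15 for i in range(1, 5)}
        n_t = 60
        a = [make_bold(labels, n_t, coher_hi, seed=s) for s in range(4)]
        b = [make_bold(labels, n_t, coher_lo, seed=100 + s) for s in range(4)]
        out = roi_reho_compare(a, b, labels, labels)
        assert (out["mean_diff"] > 0).mean() >= 0.9

    def test_mismatched_roi_sets_error(self):
        labels = self._labels()
        other = LabelMap((labels.data == 1).astype(np.int32), np.eye(4), {1: "r1"})
        with pytest.raises(ValueError, match="differ"):
            roi_reho_compare([np.zeros((8, 8, 8, 12))] * 2,
                             [np.zeros((8, 8, 8, 12))] * 2, labels, other)
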