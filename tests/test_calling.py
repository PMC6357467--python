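"""DMR calling: difference track, smoothing, segmentation, permutation."""

import numpy as np
import pandas as pd
import pytest

from dmrkit.calling import (
    DMRCallingParams,
    DifferenceTrack,
    call_dmrs,
    detect_candidate_regions,
    group_methylation_difference,
    permutation_test,
    region_sample_methylation,
    score_regions,
    smooth_difference,
)
from dmrkit.io import MethylationMatrix
from dmrkit.regions import RegionSet


def _matrix(pos, meth, total, samples, chrom="chr1"):
    meth = np.asarray(meth)
    total = np.asarray(total)
    return MethylationMatrix(
        chrom=np.array([chrom] * len(pos), dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        meth=meth,
        total=total,
        samples=samples,
    )


def _track(pos, d, w=None, chrom=None):
    n = len(pos)
    w = np.ones(n) if w is None else np.asarray(w, float)
    chrom = np.array(["chr1"] * n, dtype=object) if chrom is None else chrom
    d = np.asarray(d, float)
    t = np.full(n, 10.0)
    return DifferenceTrack(
        chrom=chrom, pos=np.asarray(pos, np.int64), d=d, w=w,
        ma=(d + 1) / 2 * t, ta=t, mb=np.full(n, 5.0), tb=t,
    )


class TestGroupDifference:
    def test_pooled_proportion_arithmetic(self):
        m = _matrix([100], [[8, 6, 2, 4]], [[10, 10, 10, 10]], ["a1", "a2", "b1", "b2"])
        track = group_methylation_difference(m, ["a1", "a2"], ["b1", "b2"])
        assert track.d[0] == pytest.approx(14 / 20 - 6 / 20)
        assert track.w[0] == pytest.approx(np.sqrt(40))

    def test_identical_groups_give_zero_difference(self):
        m = _matrix(
            [10, 20], [[3, 3, 3, 3], [1, 1, 1, 1]], [[5, 5, 5, 5], [4, 4, 4, 4]],
            ["a1", "a2", "b1", "b2"],
        )
        track = group_methylation_difference(m, ["a1", "a2"], ["b1", "b2"])
        np.testing.assert_allclose(track.d, 0)

    def test_random_counts_match_pooled_oracle(self):
        rng = np.random.default_rng(3)
        n, k = 50, 6
        total = rng.integers(1, 20, size=(n, k))
        meth = rng.binomial(total, 0.5)
        ids = [f"s{i}" for i in range(k)]
        m = _matrix(np.arange(n) * 100, meth, total, ids)
        track = group_methylation_difference(m, ids[:3], ids[3:])
        for i in range(n):
            pa = meth[i, :3].sum() / total[i, :3].sum()
            pb = meth[i, 3:].sum() / total[i, 3:].sum()
            assert track.d[i] == pytest.approx(pa - pb)

    def test_requires_two_samples_per_group(self):
        m = _matrix([10], [[1, 1, 1]], [[2, 2, 2]], ["a1", "b1", "b2"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            group_methylation_difference(m, ["a1"], ["b1", "b2"])


class TestSmoothing:
    def test_isolated_cpg_keeps_raw_difference(self):
        track = _track([100], [0.42])
        smooth_difference(track, window_bp=500, max_gap=1000)
        assert track.s[0] == pytest.approx(0.42)

    def test_constant_track_is_fixed_point(self):
        track = _track(np.arange(0, 2000, 100), np.full(20, 0.3))
        smooth_difference(track)
        np.testing.assert_allclose(track.s, 0.3)

    def test_matches_quadratic_windowed_mean_oracle(self):
        rng = np.random.default_rng(11)
        pos = np.sort(rng.choice(50_000, size=120, replace=False))
        d = rng.uniform(-1, 1, size=120)
        w = rng.uniform(0.5, 5.0, size=120)
        window, max_gap = 700, 1500
        track = _track(pos, d, w)
        smooth_difference(track, window_bp=window, max_gap=max_gap)
        gaps = np.diff(pos)
        for i in range(len(pos)):
            num = den = 0.0
            for j in range(len(pos)):
                if abs(int(pos[j]) - int(pos[i])) > window:
                    continue
                lo, hi = min(i, j), max(i, j)
                if lo < hi and np.any(gaps[lo:hi] > max_gap):
                    continue  # window never bridges a large gap
                num += w[j] * d[j]
                den += w[j]
            assert track.s[i] == pytest.approx(num / den, abs=1e-12)


def _oracle_segments(pos, s, cutoff, min_cpgs, max_gap):
    """Plain-loop segmentation used as an independent oracle."""
    runs, cur = [], []
    for i in range(len(pos)):
        ok = abs(s[i]) >= cutoff
        if cur:
            same_sign = (s[i] > 0) == (s[cur[-1]] > 0)
            close = pos[i] - pos[cur[-1]] <= max_gap
            if not (ok and same_sign and close):
                runs.append(cur)
                cur = []
        if ok and not cur:
            cur = [i]
        elif ok:
            cur.append(i)
    if cur:
        runs.append(cur)
    return [(r[0], r[-1] + 1) for r in runs if len(r) >= min_cpgs]


class TestSegmentation:
    def test_all_zero_track_yields_nothing(self):
        track = _track([10, 20, 30], [0.0, 0.0, 0.0])
        track.s = track.d
        assert detect_candidate_regions(track, 0.1, 2, 1000).empty

    def test_hand_worked_run_with_subthreshold_tail(self):
        track = _track([100, 150, 200, 250, 300], [0.2, 0.15, 0.12, 0.05, -0.2])
        track.s = track.d.copy()
        cands = detect_candidate_regions(track, cutoff=0.1, min_cpgs=3, max_gap=1000)
        assert len(cands) == 1
        row = cands.iloc[0]
        assert (row["start"], row["end"]) == (100, 202)
        assert (row["idx_start"], row["idx_end"]) == (0, 3)

    def test_sign_flip_splits_run(self):
        track = _track([0, 100, 200, 300], [0.3, 0.3, -0.3, -0.3])
        track.s = track.d.copy()
        cands = detect_candidate_regions(track, cutoff=0.1, min_cpgs=2, max_gap=1000)
        assert len(cands) == 2
        assert list(cands["idx_start"]) == [0, 2]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_loop_oracle_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(20_000, size=200, replace=False))
        s = rng.uniform(-0.4, 0.4, size=200)
        track = _track(pos, s)
        track.s = s
        cands = detect_candidate_regions(track, cutoff=0.15, min_cpgs=3, max_gap=600)
        got = list(zip(cands["idx_start"], cands["idx_end"]))
        assert got == _oracle_segments(pos, s, 0.15, 3, 600)

    def test_lower_cutoff_never_reduces_candidates(self):
        rng = np.random.default_rng(5)
        pos = np.arange(0, 30_000, 150)
        s = rng.uniform(-0.4, 0.4, size=len(pos))
        track = _track(pos, s)
        track.s = s
        counts = [
            len(detect_candidate_regions(track, cutoff=c, min_cpgs=3, max_gap=1000))
            for c in (0.3, 0.2, 0.1, 0.05)
        ]
        assert counts == sorted(counts)


class TestScoring:
    def test_area_is_sum_of_smoothed_values(self):
        track = _track([0, 100, 200], [0.2, 0.2, 0.2])
        track.s = track.d.copy()
        cands = detect_candidate_regions(track, 0.1, 3, 1000)
        scored = score_regions(cands, track)
        assert scored.iloc[0]["area"] == pytest.approx(0.6)
        assert scored.iloc[0]["n_cpgs"] == 3

    def test_direction_follows_percent_difference_sign(self, small_call):
        c = small_call.candidates
        assert (np.sign(c["area"]) == np.sign(c["meth_diff_pct"])).all()
        assert ((c["meth_diff_pct"] > 0) == (c["direction"] == "hyper")).all()


class TestPermutation:
    def test_identical_samples_give_unit_pvalues(self):
        # all samples share the same counts: every permuted track equals the
        # observed (flat) one, so with ties counted as exceedances every
        # candidate window scores p_emp = fwer = 1
        n = 30
        pos = np.arange(n) * 100
        total = np.full((n, 6), 10)
        ids = [f"s{i}" for i in range(6)]
        same = _matrix(pos, np.full((n, 6), 5), total, ids)
        track = group_methylation_difference(same, ids[:3], ids[3:])
        smooth_difference(track)
        # externally supplied candidate windows (the track itself is flat)
        cands = score_regions(
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000],
                          "idx_start": [0], "idx_end": [10]}),
            track,
        )
        out, null = permutation_test(same, cands, ids[:3], ids[3:], n_perm=50, seed=0)
        assert (out["p_emp"] == 1.0).all() and (out["fwer"] == 1.0).all()

    def test_three_vs_three_enumerates_twenty_assignments(self, small_cohort):
        _, _, cohort = small_cohort
        m = cohort.matrix
        ids = m.samples[:6]
        track = group_methylation_difference(m, ids[:3], ids[3:])
        smooth_difference(track)
        cands = score_regions(detect_candidate_regions(track, 0.1, 5, 1000), track)
        _, null = permutation_test(m, cands, ids[:3], ids[3:], n_perm=1000, seed=0)
        assert null.enumerated and null.n_perm == 20

    def test_single_sample_groups_rejected(self):
        m = _matrix([10], [[1, 1]], [[2, 2]], ["a", "b"])
        cands = pd.DataFrame({"chrom": [], "start": [], "end": [], "idx_start": [],
                              "idx_end": [], "area": []})
        with pytest.raises(ValueError, match="single sample"):
            permutation_test(m, cands, ["a"], ["b"], n_perm=10, seed=0)


class TestCallDmrs:
    def test_swapping_groups_negates_statistics(self, small_cohort):
        _, _, cohort = small_cohort
        sub = cohort.sample_sheet[cohort.sample_sheet["sample"].isin(
            ["WD_01", "WD_02", "WD_03", "HC_01", "HC_02", "HC_03"])]
        params = DMRCallingParams(n_perm=1000, seed=3)  # 3v3 -> fully enumerated
        ab = call_dmrs(cohort.matrix, sub, "WD", "HC", params)
        ba = call_dmrs(cohort.matrix, sub, "HC", "WD", params)
        np.testing.assert_allclose(ab.track.d, -ba.track.d)
        np.testing.assert_allclose(ab.track.s, -ba.track.s)
        a, b = ab.candidates, ba.candidates
        assert list(a["start"]) == list(b["start"])
        np.testing.assert_allclose(a["area"], -b["area"])
        np.testing.assert_allclose(a["meth_diff_pct"], -b["meth_diff_pct"])
        np.testing.assert_allclose(a["p_emp"], b["p_emp"])
        np.testing.assert_allclose(a["fwer"], b["fwer"])

    def test_same_seed_reproduces_call(self, small_cohort, small_call):
        _, _, cohort = small_cohort
        again = call_dmrs(
            cohort.matrix, cohort.sample_sheet, "WD", "HC", DMRCallingParams(n_perm=200, seed=5)
        )
        pd.testing.assert_frame_equal(again.candidates, small_call.candidates)

    def test_sample_order_within_groups_is_irrelevant(self, small_cohort):
        _, _, cohort = small_cohort
        sheet = cohort.sample_sheet
        shuffled = pd.concat([sheet[sheet.group == g].iloc[::-1] for g in ("WD", "HC")])
        params = DMRCallingParams(n_perm=50, seed=1)
        r1 = call_dmrs(cohort.matrix, sheet, "WD", "HC", params)
        r2 = call_dmrs(cohort.matrix, shuffled, "WD", "HC", params)
        np.testing.assert_allclose(r1.track.d, r2.track.d)
        np.testing.assert_allclose(
            r1.candidates["area"].to_numpy(), r2.candidates["area"].to_numpy()
        )

    def test_recovers_planted_regions(self, small_cohort, small_call):
        _, truth, _ = small_cohort
        sig = small_call.significant(0.05, "q")
        planted = truth.planted_regions()
        assert planted.overlaps_any(RegionSet(sig)).mean() >= 0.7
        assert (~RegionSet(sig).overlaps_any(planted)).sum() == 0


class TestRegionSampleMethylation:
    def test_two_cpg_arithmetic(self):
        m = _matrix([100, 110], [[3], [1]], [[5], [5]], ["s1"])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [90], "end": [120]})
        table = region_sample_methylation(m, regions)
        assert table.iloc[0, 0] == pytest.approx(40.0)

    def test_fully_methylated_region_is_100(self):
        m = _matrix([100, 110], [[5], [5]], [[5], [5]], ["s1"])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [200]})
        assert region_sample_methylation(m, regions).iloc[0, 0] == pytest.approx(100.0)

    def test_zero_coverage_flagged_missing(self):
        m = _matrix([100], [[0]], [[0]], ["s1"])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [200]})
        assert np.isnan(region_sample_methylation(m, regions).iloc[0, 0])

    def test_matches_brute_force_on_random_data(self, small_cohort):
        _, _, cohort = small_cohort
        m = cohort.matrix
        rng = np.random.default_rng(0)
        starts = rng.choice(900_000, size=5)
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 5_000}
        )
        table = region_sample_methylation(m, regions)
        for r, (s, e) in enumerate(zip(regions["start"], regions["end"])):
            in_region = (m.pos >= s) & (m.pos < e)
            for j, sid in enumerate(m.samples):
                t = m.total[in_region, j].sum()
                expect = 100.0 * m.meth[in_region, j].sum() / t if t else np.nan
                got = table.iloc[r, j]
                assert (np.isnan(got) and np.isnan(expect)) or got == pytest.approx(expect)
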