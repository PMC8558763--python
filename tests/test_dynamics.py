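import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import xdosage as xd
from xdosage import dynamics

from conftest import make_matrix


class TestAllelicRatio:
    @pytest.mark.parametrize("mus,cast,expected", [
        (5, 5, 0.5), (0, 12, 0.0), (12, 0, 1.0), (3, 9, 0.25)])
    def test_values(self, mus, cast, expected):
        assert xd.allelic_ratio(mus, cast) == pytest.approx(expected)

    def test_undefined_at_zero_reads(self):
        with pytest.raises(ValueError):
            xd.allelic_ratio(0, 0)

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_swap_symmetry(self, m, c):
        if m + c == 0:
            return
        assert xd.allelic_ratio(m, c) + xd.allelic_ratio(c, m) == \
            pytest.approx(1.0)


class TestAccessibilityState:
    @pytest.mark.parametrize("ratio,state", [
        (0.5, "biallelic"), (0.10, "cast_mono"), (0.95, "mus_mono"),
        (0.15, "biallelic"), (0.85, "biallelic"),  # boundaries are biallelic
        (0.0, "cast_mono"), (1.0, "mus_mono")])
    def test_bands(self, ratio, state):
        assert xd.classify_accessibility_state(ratio) == state

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            xd.classify_accessibility_state(1.2)

    @given(st.floats(0.0, 1.0, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition(self, r):
        assert xd.classify_accessibility_state(r) in (
            "cast_mono", "biallelic", "mus_mono")


class TestInformativeRegions:
    def test_nine_count_threshold_in_every_group(self):
        # sums per group: f0 always 9 -> kept; f1 has one group at 8 -> dropped
        mus = np.array([[5, 5, 5], [4, 4, 4]])
        cast = np.array([[4, 4, 4], [5, 5, 4]])
        m = make_matrix(mus, cast, ["chrX", "chrX"],
                        samples=["d0", "d8", "d9"])
        groups = pd.Series({"d0": "d0", "d8": "d8", "d9": "d9"})
        kept = xd.filter_informative_regions(m, groups, min_total_per_group=9)
        assert list(kept) == ["f0"]
        all_kept = xd.filter_informative_regions(m, groups,
                                                 min_total_per_group=0)
        assert len(all_kept) == 2


class TestClustering:
    def test_two_planted_archetypes_recovered(self, rng):
        flat0 = np.clip(rng.normal(0.02, 0.01, size=(40, 6)), 0, 1)
        flat5 = np.clip(rng.normal(0.5, 0.01, size=(40, 6)), 0, 1)
        traj = pd.DataFrame(np.vstack([flat0, flat5]),
                            columns=list(dynamics.TIMEPOINTS))
        labels, centers = xd.cluster_ratio_trajectories(traj, k=2, seed=0)
        assert labels.iloc[:40].nunique() == 1
        assert labels.iloc[40:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]
        assert sorted(np.round(centers.mean(axis=1), 1)) == [0.0, 0.5]

    def test_k_one_center_is_grand_mean(self, rng):
        traj = pd.DataFrame(rng.uniform(size=(30, 6)),
                            columns=list(dynamics.TIMEPOINTS))
        _, centers = xd.cluster_ratio_trajectories(traj, k=1, seed=0)
        assert np.allclose(centers.iloc[0], traj.mean(axis=0), atol=1e-9)

    def test_k_exceeding_features_errors(self, rng):
        traj = pd.DataFrame(rng.uniform(size=(5, 6)))
        with pytest.raises(ValueError):
            xd.cluster_ratio_trajectories(traj, k=10, seed=0)

    def test_feature_order_permutation_invariance(self, rng):
        # four planted archetypes: the recovered partition must not depend
        # on the order the features are presented in
        levels = np.repeat([0.05, 0.3, 0.6, 0.9], 15)[:, None]
        traj = pd.DataFrame(
            np.clip(levels + rng.normal(0, 0.02, size=(60, 6)), 0, 1),
            index=[f"r{i}" for i in range(60)])
        l1, _ = xd.cluster_ratio_trajectories(traj, k=4, seed=0)
        perm = rng.permutation(60)
        l2, _ = xd.cluster_ratio_trajectories(traj.iloc[perm], k=4, seed=0)
        # same partition up to relabeling
        joint = pd.crosstab(l1.loc[l2.index], l2)
        assert (joint.gt(0).sum(axis=1) == 1).all()


class TestCategories:
    @pytest.mark.parametrize("traj,expected", [
        ((0.02, 0.35, 0.40, 0.45, 0.50, 0.50), "early"),
        ((0.02, 0.02, 0.40, 0.45, 0.50, 0.50), "intermediate"),
        ((0.02, 0.02, 0.02, 0.45, 0.50, 0.50), "late"),
        ((0.02, 0.02, 0.02, 0.02, 0.50, 0.50), "very_late"),
        ((0.50, 0.50, 0.50, 0.50, 0.50, 0.50), "escapee"),
        ((0.02, 0.02, 0.02, 0.02, 0.02, 0.02), "cast_monoallelic"),
        ((0.95, 0.90, 0.60, 0.55, 0.50, 0.50), "mus_mono_to_bi"),
    ])
    def test_first_crossing_rules(self, traj, expected):
        means = pd.DataFrame([traj], columns=list(dynamics.TIMEPOINTS))
        assert xd.assign_categories(means).iloc[0] == expected


class TestDistance:
    def test_overlap_and_gap_conventions(self):
        feats = pd.DataFrame({"chrom": ["chr1", "chr1"],
                              "start": [1000, 2050], "end": [1100, 2150]},
                             index=["q0", "q1"])
        ref = pd.DataFrame({"chrom": ["chr1"], "start": [2000], "end": [2100]})
        d = xd.distance_to_nearest_biallelic(feats, ref)
        assert d["q0"] == 900.0   # gap between closest edges
        assert d["q1"] == 0.0     # overlap

    def test_chromosome_without_reference_gives_nan(self):
        feats = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [10]},
                             index=["q"])
        ref = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        assert np.isnan(xd.distance_to_nearest_biallelic(feats, ref)["q"])

    def test_matches_brute_force_oracle(self, rng):
        def brute(feats, ref):
            out = {}
            for fid, f in feats.iterrows():
                best = np.inf
                for _, r in ref.iterrows():
                    if r["chrom"] != f["chrom"]:
                        continue
                    if r["start"] < f["end"] and r["end"] > f["start"]:
                        gap = 0.0
                    elif r["start"] >= f["end"]:
                        gap = r["start"] - f["end"]
                    else:
                        gap = f["start"] - r["end"]
                    best = min(best, gap)
                out[fid] = best if np.isfinite(best) else np.nan
            return pd.Series(out)

        def random_regions(n):
            start = rng.integers(0, 100_000, size=n)
            return pd.DataFrame({
                "chrom": rng.choice(["chr1", "chr2"], size=n),
                "start": start, "end": start + rng.integers(50, 500, size=n)},
                index=[f"r{i}" for i in range(n)])

        feats, ref = random_regions(50), random_regions(30)
        fast = xd.distance_to_nearest_biallelic(feats, ref)
        pd.testing.assert_series_equal(fast, brute(feats, ref),
                                       check_names=False)


class TestOpeningTime:
    def test_exponential_trajectory_recovers_crossing_day(self):
        # ratio = exp(b0 + b1*day) crossing 0.15 exactly at day 9
        days = dynamics.DAY_MAP
        b1 = 0.1
        b0 = np.log(0.15) - b1 * 9.0
        traj = pd.DataFrame(
            [[np.exp(b0 + b1 * days[t]) for t in dynamics.TIMEPOINTS]],
            columns=list(dynamics.TIMEPOINTS), index=["r0"])
        t = xd.estimate_opening_time(traj)
        assert t["r0"] == pytest.approx(9.0, abs=0.05)

    def test_escapee_opens_at_day_zero(self):
        traj = pd.DataFrame([[0.4, 0.42, 0.45, 0.45, 0.5, 0.5]],
                            columns=list(dynamics.TIMEPOINTS), index=["r0"])
        assert xd.estimate_opening_time(traj)["r0"] == 0.0

    def test_never_opening_region_is_nan(self):
        traj = pd.DataFrame([[0.02, 0.02, 0.02, 0.02, 0.02, 0.02]],
                            columns=list(dynamics.TIMEPOINTS), index=["r0"])
        assert np.isnan(xd.estimate_opening_time(traj)["r0"])

    def test_enhancers_open_before_promoters(self, rng):
        # planted: enhancer-like regions cross 0.15 around day 8,
        # promoter-like around day 10
        days = np.array([dynamics.DAY_MAP[t] for t in dynamics.TIMEPOINTS])

        def batch(cross_day, n):
            b1 = 0.12
            b0 = np.log(0.15) - b1 * cross_day
            base = np.exp(b0 + b1 * days)
            return np.clip(base[None, :] *
                           np.exp(rng.normal(0, 0.05, size=(n, len(days)))),
                           0.001, 1.0)

        traj = pd.DataFrame(np.vstack([batch(8, 30), batch(10, 30)]),
                            columns=list(dynamics.TIMEPOINTS),
                            index=[f"r{i}" for i in range(60)])
        ann = pd.DataFrame({"reg_class": ["enhancer"] * 30 + ["promoter"] * 30},
                           index=traj.index)
        t = xd.estimate_opening_time(traj)
        means = xd.mean_opening_time_by_class(t.dropna(), ann)
        assert means["enhancer"] < means["promoter"]
        assert means["enhancer"] == pytest.approx(8.0, abs=1.0)
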