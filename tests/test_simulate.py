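import numpy as np
import pandas as pd
import pytest
from scipy import stats

import xdosage as xd
from xdosage.simulate import atac_groups


SMALL = dict(n_cells=200, n_autosomal_features=300, n_x_features=60)


class TestDeterminism:
    def test_same_seed_identical_matrices(self):
        cfg = xd.SimulationConfig(**SMALL)
        m1, _, _ = xd.simulate_reprogramming_scrna(cfg, seed=42)
        m2, _, _ = xd.simulate_reprogramming_scrna(cfg, seed=42)
        pd.testing.assert_frame_equal(m1.counts_mus, m2.counts_mus)
        pd.testing.assert_frame_equal(m1.counts_total, m2.counts_total)
        m3, _, _ = xd.simulate_reprogramming_scrna(cfg, seed=43)
        assert not m1.counts_mus.equals(m3.counts_mus)

    def test_atac_same_seed_identical(self):
        cfg = xd.SimulationConfig(n_autosomal_regions=500, n_x_regions=100)
        a, _ = xd.simulate_atac_timepoints(cfg, seed=7)
        b, _ = xd.simulate_atac_timepoints(cfg, seed=7)
        pd.testing.assert_frame_equal(a.counts_cast, b.counts_cast)


class TestStructuralInvariants:
    def test_matrices_validate_and_totals_dominate(self):
        m, pt, truth = xd.simulate_reprogramming_scrna(
            xd.SimulationConfig(**SMALL), seed=0)
        m.validate()
        assert ((m.counts_mus + m.counts_cast) <= m.counts_total).all().all()
        assert truth.features.shape[0] == m.shape[0]
        assert list(pt.index) == list(m.samples)

    def test_autosomal_allelic_ratios_symmetric(self):
        cfg = xd.SimulationConfig(n_autosomal_regions=4000, n_x_regions=100)
        m, _ = xd.simulate_atac_timepoints(cfg, seed=3, timepoints=("d0",))
        auto = m.annotation.index[m.annotation["chrom"] != "chrX"]
        mus = m.counts_mus.loc[auto].sum(axis=1)
        cast = m.counts_cast.loc[auto].sum(axis=1)
        ratios = mus / (mus + cast)
        assert ratios.mean() == pytest.approx(0.5, abs=0.01)

    def test_invalid_config_rejected_before_sampling(self):
        with pytest.raises(ValueError):
            xd.simulate_reprogramming_scrna(
                xd.SimulationConfig(xa_fold=-1.0), seed=0)
        with pytest.raises(ValueError):
            xd.simulate_reprogramming_scrna(
                xd.SimulationConfig(snapshot="C9"), seed=0)
        with pytest.raises(KeyError):
            xd.preset("unknown")


class TestNullConfig:
    def test_no_upregulation_no_xci_is_symmetric(self):
        cfg = xd.SimulationConfig(
            n_cells=300, n_autosomal_features=1500, n_x_features=300,
            xa_fold=1.0, other_x="active", fraction_escapees=1.0)
        m, pt, _ = xd.simulate_reprogramming_scrna(cfg, seed=11)
        m = xd.normalize_library(m)
        fold = xd.x_autosome_fold(m, "cast").fold_change
        assert fold == pytest.approx(1.0, abs=0.07)
        x = m.annotation.index[m.annotation["chrom"] == "chrX"]
        mus = m.counts_mus.loc[x].to_numpy().sum()
        cast = m.counts_cast.loc[x].to_numpy().sum()
        assert mus / (mus + cast) == pytest.approx(0.5, abs=0.02)


class TestReprogrammingDynamics:
    def test_xi_ratio_rises_from_zero_to_one(self):
        m, pt, _ = xd.simulate_reprogramming_scrna(
            xd.SimulationConfig(**SMALL), seed=5)
        m = xd.normalize_library(xd.apply_missing_convention(m))
        ratio = xd.x_autosome_ratio_per_cell(m, "mus")
        early = ratio[pt["pseudotime"] < 10]
        late = ratio[pt["pseudotime"] > 95]
        assert early.median() < 0.1
        assert late.median() > 0.8

    def test_atac_trajectories_move_toward_one(self):
        cfg = xd.SimulationConfig(n_autosomal_regions=4000, n_x_regions=400)
        m, _ = xd.simulate_atac_timepoints(cfg, seed=9)
        m2, _ = xd.filter_min_allelic_total(m, 10, groups=atac_groups(m))
        m2 = xd.normalize_library(m2)
        cast = xd.chromosome_autosome_trajectory(m2, "chrX", "cast",
                                                 atac_groups(m))
        mus = xd.chromosome_autosome_trajectory(m2, "chrX", "mus",
                                                atac_groups(m))
        # Xa enhancement decays toward 1; Xi rises toward 1
        assert cast["d0"] > 1.2 and cast["iPSC"] == pytest.approx(1.0, abs=0.1)
        assert mus["d0"] < 0.3 and mus["iPSC"] > 0.8
        assert (np.diff(mus.to_numpy()) > -0.05).all()

    def test_planted_early_region_classified_early(self):
        cfg = xd.SimulationConfig(n_autosomal_regions=200, n_x_regions=400)
        m, truth = xd.simulate_atac_timepoints(cfg, seed=13)
        groups = atac_groups(m)
        x = m.annotation.index[m.annotation["chrom"] == "chrX"]
        keep = xd.filter_informative_regions(m.subset(features=x), groups)
        ratios = xd.group_allelic_ratios(m.subset(features=keep), groups)
        cats, _, _ = xd.categorize_regions(ratios, k=10, seed=0)
        planted = truth.features.loc[keep, "category"]
        early = planted.index[planted == "early"]
        assert (cats.loc[early] == "early").mean() >= 0.9

    def test_planted_distance_structure(self):
        cfg = xd.SimulationConfig(n_autosomal_regions=100, n_x_regions=600)
        m, truth = xd.simulate_atac_timepoints(cfg, seed=17)
        ann = m.annotation
        cats = truth.features["category"]
        ref = ann.loc[cats.index[cats == "escapee"]]
        d = xd.distance_to_nearest_biallelic(
            ann.loc[ann["chrom"] == "chrX"], ref)
        assert d.loc[cats.index[cats == "early"]].mean() < \
            d.loc[cats.index[cats == "very_late"]].mean()


class TestXo:
    def test_lost_allele_counts_zero_including_escapees(self):
        cfg = xd.SimulationConfig(**SMALL, xo_fraction=0.5,
                                  xo_lost_allele="mus")
        m, truth = xd.simulate_xo_ipscs(cfg, seed=21)
        xo = truth.cells.index[truth.cells["x_state"] == "XO_mus_lost"]
        x = m.annotation.index[m.annotation["chrom"] == "chrX"]
        esc = m.annotation.index[m.annotation["category"] == "escapee"]
        assert len(esc) > 0
        assert (m.counts_mus.loc[x, xo] == 0).all().all()
        assert (m.counts_mus.loc[esc, xo] == 0).all().all()

    def test_retained_allele_upregulated_over_xx(self):
        cfg = xd.SimulationConfig(n_cells=400, n_autosomal_features=1000,
                                  n_x_features=200, xo_fraction=0.5,
                                  xo_lost_allele="mus", xa_fold=1.35)
        m, truth = xd.simulate_xo_ipscs(cfg, seed=23)
        m = xd.normalize_library(xd.apply_missing_convention(m))
        ratio = xd.x_autosome_ratio_per_cell(m, "cast", statistic="mean")
        xo = truth.cells.index[truth.cells["x_state"] == "XO_mus_lost"]
        xx = truth.cells.index[truth.cells["x_state"] == "XX"]
        assert ratio[xo].median() > ratio[xx].median() * 1.1


class TestMarginalsMatchModel:
    def test_simulated_counts_follow_poisson_beta(self, rng):
        """Chi-square goodness of fit of simulated marginals against the
        model pmf at the generative parameters (>= 95% of genes pass)."""
        counts, params, _, _ = xd.simulate_burst_dataset(
            n_autosomal=40, n_x=0, n_cells=1000, seed=31)
        passed = 0
        for gene in counts.index:
            x = counts.loc[gene].to_numpy()
            k_on, k_off, k_syn = params.loc[gene, ["k_on", "k_off", "k_syn"]]
            hi = int(x.max()) + 1
            pmf = xd.poisson_beta_pmf(np.arange(hi), k_on, k_off, k_syn)
            # pool bins to expected counts >= 5
            obs = np.bincount(x, minlength=hi).astype(float)
            exp = pmf * len(x)
            exp = np.append(exp, max(len(x) - exp.sum(), 1e-9))
            obs = np.append(obs, 0.0)
            order = np.argsort(-exp)
            obs, exp = obs[order], exp[order]
            cut = np.searchsorted(np.cumsum(exp), len(x) - 5.0)
            o = np.append(obs[:cut], obs[cut:].sum())
            e = np.append(exp[:cut], exp[cut:].sum())
            p = stats.chisquare(o, e * o.sum() / e.sum()).pvalue
            passed += p > 0.01
        assert passed >= 0.95 * len(counts)
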