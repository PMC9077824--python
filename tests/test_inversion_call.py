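"""Four-step inversion test: regional LD, PCA karyotyping, het contrasts,
arrangement frequencies."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radpop import forward_sim as fs
from radpop.inversion_call import (
    HET,
    HOM_A,
    HOM_B,
    GenomicRegion,
    KaryotypeCall,
    het_by_cluster,
    karyotype_frequencies,
    regional_ld_summary,
    regional_pca_karyotype,
)
from radpop.linkage import pairwise_r2
from radpop.variant_io import PopulationMap

from conftest import make_gm, make_variants

REGION = GenomicRegion("chr8", 15_260_000, 15_900_000)


def make_call(karyotype, het, samples=None, pc1=None):
    karyotype = np.asarray(karyotype, dtype=object)
    n = len(karyotype)
    cluster = np.array([{HOM_A: 1, HET: 2, HOM_B: 3}[k] for k in karyotype])
    return KaryotypeCall(
        samples=samples or [f"i{i}" for i in range(n)],
        cluster=cluster,
        karyotype=karyotype,
        het=np.asarray(het, dtype=float),
        pc1=pc1 if pc1 is not None else cluster.astype(float),
        n_clusters_found=len(set(karyotype)),
    )


class TestGenomicRegion:
    def test_parse_with_commas(self):
        r = GenomicRegion.parse("chr8:15,260,000-15,900,000")
        assert (r.chrom, r.start, r.end) == ("chr8", 15_260_000, 15_900_000)

    def test_parse_plain(self):
        r = GenomicRegion.parse("scaffold_12:100-200")
        assert (r.chrom, r.start, r.end) == ("scaffold_12", 100, 200)

    def test_inverted_bounds_raise(self):
        with pytest.raises(ValueError):
            GenomicRegion("chr1", 200, 100)


class TestRegionalLd:
    def _gm_with_region(self, seed=0):
        """Ten perfectly correlated region SNPs amid 40 independent ones."""
        rng = np.random.default_rng(seed)
        carrier = rng.binomial(2, 0.5, 100)
        G = rng.binomial(2, 0.5, size=(100, 50)).astype(np.int8)
        G[:, 20:30] = carrier[:, None]
        v = make_variants(50, chrom="chr1", spacing=1000)
        region = GenomicRegion("chr1", 20_500, 30_500)  # SNPs 20..29 (pos 21k-30k)
        return make_gm(G), v, region

    def test_counts_and_elevation(self):
        gm, v, region = self._gm_with_region()
        pairs = pairwise_r2(gm)
        summ = regional_ld_summary(pairs, region, gm.variants)
        assert summ["n_region_pairs"] == 45  # C(10,2)
        assert summ["mean_r2"] == pytest.approx(1.0)
        assert summ["max_r2"] == pytest.approx(1.0)
        assert summ["background_mean_r2"] < 0.1
        assert summ["n_region_pairs"] + summ["n_background_pairs"] == 50 * 49 // 2

    def test_report_floor_echoed(self):
        gm, v, region = self._gm_with_region(1)
        pairs = pairwise_r2(gm, report_floor=0.05)
        summ = regional_ld_summary(pairs, region, gm.variants)
        assert summ["report_floor"] == 0.05
        assert summ["mean_r2"] >= 0.05

    def test_too_few_region_snps_raise(self):
        gm, v, _ = self._gm_with_region(2)
        with pytest.raises(ValueError):
            regional_ld_summary(pairwise_r2(gm), GenomicRegion("chr1", 1, 1500),
                                gm.variants)


class TestKaryotypePca:
    def _three_cluster_gm(self, seed=0, n_per=(45, 30, 15), n_snps=30, noise=0.0):
        """Individuals are exact 0/1/2 dosage stacks over region SNPs."""
        rng = np.random.default_rng(seed)
        blocks = [np.full((k, n_snps), d) for k, d in zip(n_per, (0, 1, 2))]
        G = np.vstack(blocks).astype(np.int8)
        if noise:
            flip = rng.random(G.shape) < noise
            G[flip] = rng.integers(0, 3, flip.sum())
        v = make_variants(n_snps, chrom="chr8", spacing=1000)
        # place inside the default region
        v = type(v)(v.chrom, v.pos + 15_260_000, v.ref, v.alt, v.locus_id)
        return make_gm(G, variants=v)

    def test_three_point_masses_discreteness_one(self):
        gm = self._three_cluster_gm()
        call, disc = regional_pca_karyotype(gm, REGION, seed=0)
        assert disc == pytest.approx(1.0, abs=1e-9)
        assert call.n_clusters_found == 3
        # middle cluster is exactly the all-het block
        assert (call.karyotype[45:75] == HET).all()
        assert len(set(call.karyotype[:45])) == 1
        assert len(set(call.karyotype[75:])) == 1
        assert set(call.karyotype[:45]) != set(call.karyotype[75:])

    def test_null_region_low_discreteness(self, null_cohort):
        gm = null_cohort.gm
        v = gm.variants
        region = GenomicRegion(str(v.chrom[0]), int(v.pos[0]), int(v.pos[40]))
        call, disc = regional_pca_karyotype(gm, region, seed=0)
        # the optimal 3-level quantizer of a Gaussian explains ~81% of its
        # variance, so continuous PC1 scores sit near 0.81 — well below the
        # >= 0.9 seen for genuinely trimodal (inversion-like) scores
        assert 0.7 < disc < 0.87

    def test_cluster_labels_stable_across_seeds(self, inversion_cohort_complete):
        co = inversion_cohort_complete
        base, _ = regional_pca_karyotype(co.gm, REGION, seed=0)
        for seed in range(1, 11):
            call, _ = regional_pca_karyotype(co.gm, REGION, seed=seed)
            assert (call.cluster == base.cluster).all()

    def test_end_to_end_recovery(self, inversion_cohort_complete):
        co = inversion_cohort_complete
        call, disc = regional_pca_karyotype(co.gm, REGION, seed=0)
        assert disc >= 0.9
        truth = np.asarray(co.truth.arrangement_dosage)
        # map clusters to dosages by majority and score accuracy
        acc = max(
            (np.array([m[c] for c in call.cluster]) == truth).mean()
            for m in ({1: 0, 2: 1, 3: 2}, {1: 2, 2: 1, 3: 0})
        )
        assert acc >= 0.95

    def test_recovery_with_missingness(self, inversion_cohort):
        co = inversion_cohort
        call, disc = regional_pca_karyotype(co.gm, REGION, seed=0)
        truth = np.asarray(co.truth.arrangement_dosage)
        acc = max(
            (np.array([m[c] for c in call.cluster]) == truth).mean()
            for m in ({1: 0, 2: 1, 3: 2}, {1: 2, 2: 1, 3: 0})
        )
        assert acc >= 0.9

    def test_degenerate_two_clusters_flagged(self):
        gm = self._three_cluster_gm(n_per=(50, 0, 40))
        with pytest.warns(UserWarning, match="clusters"):
            call, _ = regional_pca_karyotype(gm, REGION, seed=0)
        # hard two-point data: one karyotype label must be absent
        assert call.flagged_degenerate or len(set(call.karyotype)) < 3


def wilcoxon_exact_perm(x, y):
    """Exact permutation two-sided p for the rank-sum statistic (oracle)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    obs = ranks[: len(x)].sum()
    n = len(pooled)
    stats_all = [
        ranks[list(c)].sum() for c in itertools.combinations(range(n), len(x))
    ]
    stats_all = np.array(stats_all)
    mu = stats_all.mean()
    return float((np.abs(stats_all - mu) >= np.abs(obs - mu) - 1e-9).mean())


class TestHetByCluster:
    def test_confirmed_on_separated_groups(self):
        het = np.r_[np.full(10, 0.10), np.full(10, 0.60), np.full(10, 0.12)]
        het += np.linspace(0, 0.01, 30)  # break ties
        call = make_call([HOM_A] * 10 + [HET] * 10 + [HOM_B] * 10, het)
        res = het_by_cluster(call)
        assert res["confirmed"] and not res["low_power"]
        assert res["medians"][HET] > max(res["medians"][HOM_A], res["medians"][HOM_B])

    def test_identical_distributions_not_confirmed(self):
        rng = np.random.default_rng(0)
        het = rng.uniform(0.1, 0.2, 36)
        call = make_call([HOM_A] * 12 + [HET] * 12 + [HOM_B] * 12, het)
        assert not het_by_cluster(call)["confirmed"]

    def test_pvalue_matches_exact_permutation_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 7)
        y = rng.uniform(0.3, 1.3, 6)
        call = make_call(
            [HOM_A] * 7 + [HET] * 6 + [HOM_B] * 7,
            np.r_[x, y, rng.uniform(0, 1, 7)],
        )
        res = het_by_cluster(call)
        p_exact = wilcoxon_exact_perm(x, y)
        # asymptotic normal approximation vs exact permutation null
        assert res["pvalues"][f"{HOM_A}_vs_{HET}"] == pytest.approx(p_exact, abs=0.03)

    def test_low_power_flag(self):
        call = make_call(
            [HOM_A] * 10 + [HET] * 2 + [HOM_B] * 10,
            np.r_[np.full(10, 0.1), [0.5, 0.6], np.full(10, 0.1)],
        )
        assert het_by_cluster(call)["low_power"]

    def test_empty_cluster_raises(self):
        call = make_call([HOM_A] * 5 + [HOM_B] * 5, np.full(10, 0.1))
        with pytest.raises(ValueError):
            het_by_cluster(call)

    def test_cohort_het_contrast_confirmed(self, inversion_cohort_complete):
        call, _ = regional_pca_karyotype(inversion_cohort_complete.gm, REGION, seed=0)
        res = het_by_cluster(call)
        assert res["confirmed"]


class TestKaryotypeFrequencies:
    def _pm(self, samples, pops):
        return PopulationMap(
            {s: p for s, p in zip(samples, pops)},
            {s: p for s, p in zip(samples, pops)},
        )

    def test_rows_sum_to_one_and_counts(self):
        karyo = [HOM_A] * 6 + [HET] * 3 + [HOM_B] * 1
        het = np.r_[np.full(6, 0.05), np.full(3, 0.5), [0.3]]
        call = make_call(karyo, het)
        pm = self._pm(call.samples, ["P1"] * 5 + ["P2"] * 5)
        out = karyotype_frequencies(call, pm)
        for tbl in (out["by_site"], out["by_population"]):
            np.testing.assert_allclose(tbl.sum(axis=1), 1.0)
        assert out["by_site"].loc["P1", HOM_A] == pytest.approx(1.0)
        assert out["by_site"].loc["P2", HET] == pytest.approx(0.6)

    def test_derived_is_lower_het_homokaryote(self):
        karyo = [HOM_A] * 4 + [HET] * 4 + [HOM_B] * 4
        het = np.r_[np.full(4, 0.30), np.full(4, 0.5), np.full(4, 0.05)]
        call = make_call(karyo, het)
        pm = self._pm(call.samples, ["P1"] * 12)
        assert karyotype_frequencies(call, pm)["assumed_derived"] == HOM_B

    def test_exact_tie_reported(self):
        karyo = [HOM_A] * 3 + [HET] * 3 + [HOM_B] * 3
        het = np.r_[np.full(3, 0.1), np.full(3, 0.5), np.full(3, 0.1)]
        call = make_call(karyo, het)
        pm = self._pm(call.samples, ["P1"] * 9)
        assert karyotype_frequencies(call, pm)["assumed_derived"] == "TIE"

    def test_hw_consistency_on_cohort(self, inversion_cohort_complete):
        co = inversion_cohort_complete
        call, _ = regional_pca_karyotype(co.gm, REGION, seed=0)
        out = karyotype_frequencies(call, co.pm)
        tbl = out["by_population"]
        np.testing.assert_allclose(tbl.sum(axis=1), 1.0)
        # arrangement frequencies in the two pools were set to 0.95 / 0.05:
        # the minor-arrangement homokaryote should be rare everywhere
        minor = tbl[[HOM_A, HOM_B]].min(axis=1)
        assert (minor < 0.05).all()
        # HW expectation for q=0.05: het fraction ~2*0.95*0.05=0.095
        assert tbl[HET].mean() == pytest.approx(0.095, abs=0.08)
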