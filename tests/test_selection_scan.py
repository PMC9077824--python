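"""EHHS / iES / XP-EHH and the sliding-window candidate regions."""

import numpy as np
import pandas as pd
import pytest

from radpop.selection_scan import (
    EhhsProfile,
    candidate_regions,
    ehhs,
    ies,
    regions_to_bed,
    xpehh_scan,
)
from radpop.variant_io import HaplotypeSet

from conftest import make_variants


def make_haps(V, variants=None, spacing=1000):
    V = np.asarray(V, dtype=np.uint8)
    v = variants if variants is not None else make_variants(V.shape[1], spacing=spacing)
    samples = [f"i{i}" for i in range(V.shape[0] // 2)]
    return HaplotypeSet(V, v, samples)


def brute_ehhs(V, pos, core, cutoff=0.05, max_gap=200_000):
    """Independent oracle: group haplotypes by their literal allele tuples."""
    n = V.shape[0]

    def hom(idx_set):
        keys = {}
        for h in range(n):
            keys.setdefault(tuple(V[h, i] for i in idx_set), []).append(h)
        return sum(len(g) * (len(g) - 1) for g in keys.values()) / (n * (n - 1))

    h0 = hom([core])
    out = {int(pos[core]): 1.0}
    for step in (1, -1):
        idx = [core]
        j = core
        while True:
            j += step
            if j < 0 or j >= V.shape[1] or abs(int(pos[j]) - int(pos[idx[-1] if step == 1 else idx[0]])) > max_gap:
                break
            idx = idx + [j] if step == 1 else [j] + idx
            e = hom(idx) / h0
            out[int(pos[j])] = e
            if e < cutoff:
                break
    ps = sorted(out)
    return np.array(ps), np.array([out[p] for p in ps])


class TestEhhs:
    def test_tiny_fixture_exact_enumeration(self, tiny_haps):
        prof = ehhs(tiny_haps, core=0)
        np.testing.assert_array_equal(prof.positions, [1000, 2000, 3000, 4000])
        np.testing.assert_allclose(prof.ehhs, [1.0, 1 / 3, 1 / 6, 1 / 6], atol=1e-12)

    def test_core_value_is_one_and_bounded(self):
        rng = np.random.default_rng(0)
        V = rng.integers(0, 2, size=(40, 30), dtype=np.uint8)
        prof = ehhs(make_haps(V), core=15)
        core_at = np.where(prof.positions == 16_000)[0][0]
        assert prof.ehhs[core_at] == 1.0
        assert np.all((prof.ehhs >= 0) & (prof.ehhs <= 1 + 1e-12))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        V = rng.integers(0, 2, size=(20, 25), dtype=np.uint8)
        haps = make_haps(V)
        for core in (0, 7, 24):
            prof = ehhs(haps, core, cutoff=0.0)  # no early stop: full profiles
            ps, es = brute_ehhs(V, haps.variants.pos, core, cutoff=0.0)
            np.testing.assert_array_equal(prof.positions, ps)
            np.testing.assert_allclose(prof.ehhs, es, atol=1e-12)

    def test_invariant_to_allele_relabel_and_hap_order(self):
        rng = np.random.default_rng(2)
        V = rng.integers(0, 2, size=(30, 20), dtype=np.uint8)
        base = ehhs(make_haps(V), 10)
        flipped = ehhs(make_haps(1 - V), 10)
        shuffled = ehhs(make_haps(V[rng.permutation(30)]), 10)
        np.testing.assert_allclose(base.ehhs, flipped.ehhs, atol=1e-12)
        np.testing.assert_allclose(base.ehhs, shuffled.ehhs, atol=1e-12)

    def test_max_gap_truncates(self):
        V = np.tile(np.array([[0], [1]], dtype=np.uint8), (5, 6))
        v = make_variants(6)
        pos = v.pos.copy()
        pos[4:] += 500_000  # open a gap between SNP 3 and 4
        v2 = type(v)(v.chrom, pos, v.ref, v.alt, v.locus_id)
        prof = ehhs(HaplotypeSet(V, v2, [f"i{i}" for i in range(5)]), core=0,
                    max_gap_bp=200_000)
        assert prof.positions.max() == 4000

    def test_cutoff_stops_extension(self):
        rng = np.random.default_rng(3)
        V = rng.integers(0, 2, size=(60, 200), dtype=np.uint8)
        prof = ehhs(make_haps(V), core=100, cutoff=0.05)
        # once below cutoff a direction stops: at most one sub-cutoff value
        # on each side of the core
        left = prof.ehhs[prof.positions < 101_000]
        right = prof.ehhs[prof.positions > 101_000]
        assert (left < 0.05).sum() <= 1 and (right < 0.05).sum() <= 1

    def test_monotone_nonincreasing_outward(self):
        # adding SNPs can only split identity groups, so EHHS cannot rise
        rng = np.random.default_rng(4)
        V = rng.integers(0, 2, size=(30, 40), dtype=np.uint8)
        prof = ehhs(make_haps(V), core=20, cutoff=0.0)
        core_at = int(np.where(prof.positions == 21_000)[0][0])
        right = prof.ehhs[core_at:]
        left = prof.ehhs[: core_at + 1][::-1]
        assert np.all(np.diff(right) <= 1e-12)
        assert np.all(np.diff(left) <= 1e-12)


class TestIes:
    def test_single_point_is_zero(self):
        prof = EhhsProfile(0, np.array([500]), np.array([1.0]), 0.05)
        assert ies(prof) == 0.0

    def test_rectangle(self):
        prof = EhhsProfile(0, np.array([0, 1000]), np.array([1.0, 1.0]), 0.05)
        assert ies(prof) == pytest.approx(1000.0)

    def test_hand_trapezoid(self):
        prof = EhhsProfile(0, np.array([0, 1000]), np.array([1.0, 0.5]), 0.05)
        assert ies(prof) == pytest.approx(750.0)

    def test_lower_cutoff_never_shrinks_integral(self):
        rng = np.random.default_rng(5)
        V = rng.integers(0, 2, size=(40, 60), dtype=np.uint8)
        haps = make_haps(V)
        for core in (10, 30, 50):
            lo = ies(ehhs(haps, core, cutoff=0.01))
            hi = ies(ehhs(haps, core, cutoff=0.20))
            assert lo >= hi - 1e-9


class TestXpehhScan:
    def _random_pair(self, seed, n=60, L=120):
        rng = np.random.default_rng(seed)
        v = make_variants(L)
        A = make_haps(rng.integers(0, 2, size=(n, L), dtype=np.uint8), v)
        B = make_haps(rng.integers(0, 2, size=(n, L), dtype=np.uint8), v)
        return A, B

    def test_identical_cohorts_zero_raw(self):
        A, _ = self._random_pair(0)
        out = xpehh_scan(A, A)
        np.testing.assert_allclose(out.table["raw"].to_numpy(), 0.0, atol=1e-12)

    def test_antisymmetry(self):
        A, B = self._random_pair(1)
        ab = xpehh_scan(A, B).table
        ba = xpehh_scan(B, A).table
        np.testing.assert_allclose(ab["raw"], -ba["raw"], atol=1e-12)
        np.testing.assert_allclose(ab["std"], -ba["std"], atol=1e-9)

    def test_shared_pool_null_controls_fdr(self):
        rng = np.random.default_rng(2)
        pool = rng.integers(0, 2, size=(200, 150), dtype=np.uint8)
        v = make_variants(150)
        idx = rng.permutation(200)
        A = make_haps(pool[idx[:100]], v)
        B = make_haps(pool[idx[100:]], v)
        out = xpehh_scan(A, B).table
        assert (out["q"] < 0.05).mean() <= 0.05

    def test_sweep_region_favors_swept_population(self):
        rng = np.random.default_rng(3)
        L, n = 1000, 100
        v = make_variants(L)
        B = rng.integers(0, 2, size=(n, L), dtype=np.uint8)
        A = rng.integers(0, 2, size=(n, L), dtype=np.uint8)
        # hard partial sweep in A over SNPs 480..520: 90% of haplotypes
        # carry one ancestral haplotype through the region
        swept = rng.integers(0, 2, size=520 - 480, dtype=np.uint8)
        carriers = rng.choice(n, int(0.9 * n), replace=False)
        A[np.ix_(carriers, np.arange(480, 520))] = swept
        out = xpehh_scan(make_haps(A, v), make_haps(B, v))
        sig = out.table[(out.table["q"] < 0.05)]
        in_mask = (sig["pos"] >= 481_000) & (sig["pos"] <= 520_000)
        in_region = sig[in_mask]
        assert len(in_region) >= 10
        assert len(sig[~in_mask]) < len(in_region) / 2  # signal dominates
        assert (in_region["population_favored"] == "A").all()
        # and the swept population has the longer homozygosity there
        assert (in_region["ies_a"] > in_region["ies_b"]).all()

    def test_mismatched_tables_raise(self):
        A, _ = self._random_pair(4)
        _, B = self._random_pair(5, L=121)
        with pytest.raises(ValueError):
            xpehh_scan(A, B)

    def test_min_finite_raises(self):
        A, B = self._random_pair(6, L=30)
        with pytest.raises(ValueError):
            xpehh_scan(A, B, min_finite=50)


def fake_scan_table(chrom, pos, qs, stds, alpha=0.05):
    from radpop.selection_scan import XpehhTable

    n = len(pos)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=np.int64),
            "locus_id": [f"m{i}" for i in range(n)],
            "ies_a": 1.0,
            "ies_b": 1.0,
            "raw": np.asarray(stds, dtype=float),
            "std": np.asarray(stds, dtype=float),
            "p": 0.5,
            "q": np.asarray(qs, dtype=float),
            "population_favored": np.where(np.asarray(stds) > 0, "A", "B"),
        }
    )
    return XpehhTable(df, alpha, 0)


class TestCandidateRegions:
    def test_no_significant_snps_no_regions(self):
        t = fake_scan_table(["chr1"] * 5, [1e4, 2e4, 3e4, 4e4, 5e4], [0.5] * 5, [1] * 5)
        regions, ann = candidate_regions(t)
        assert regions == []
        assert not ann["in_region"].any()

    def test_three_clustered_hits_one_region(self):
        t = fake_scan_table(
            ["chr1"] * 4,
            [10_000, 20_000, 30_000, 900_000],
            [0.01, 0.01, 0.01, 0.5],
            [2.0, 2.0, 2.0, 0.1],
        )
        regions, ann = candidate_regions(t)
        assert len(regions) == 1
        r = regions[0]
        assert r.n_sig == 3 and r.population_favored == "A"
        assert r.start <= 10_000 and r.end >= 30_000
        assert ann["in_region"].tolist() == [True, True, True, False]

    def test_two_hits_insufficient(self):
        t = fake_scan_table(
            ["chr1"] * 3, [10_000, 20_000, 900_000], [0.01, 0.01, 0.5], [2, 2, 0]
        )
        regions, _ = candidate_regions(t)
        assert regions == []

    def test_matches_exhaustive_window_enumeration(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), 300, replace=False))
        qs = rng.uniform(0, 1, 300) ** 3
        stds = rng.normal(0, 2, 300)
        t = fake_scan_table(["chr1"] * 300, pos, qs, stds)
        regions, _ = candidate_regions(t)

        # oracle: enumerate every window start, merge qualifying intervals
        sig_pos = pos[qs < 0.05]
        merged = []
        for s in range(1, int(pos.max()) + 1, 10_000):
            e = s + 100_000 - 1
            if ((sig_pos >= s) & (sig_pos <= e)).sum() >= 3:
                if merged and s <= merged[-1][1] + 1:
                    merged[-1][1] = e
                else:
                    merged.append([s, e])
        assert [(r.start, r.end) for r in regions] == [tuple(m) for m in merged]
        for r in regions:
            assert r.n_sig == ((sig_pos >= r.start) & (sig_pos <= r.end)).sum()

    def test_regions_disjoint_and_sorted(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), 400, replace=False))
        t = fake_scan_table(
            ["chr1"] * 400, pos, rng.uniform(0, 1, 400) ** 4, rng.normal(0, 2, 400)
        )
        regions, _ = candidate_regions(t)
        assert len(regions) >= 1
        for a, b in zip(regions, regions[1:]):
            assert a.end < b.start  # merged -> strictly disjoint

    def test_chromosomes_kept_separate(self):
        t = fake_scan_table(
            ["chr1", "chr1", "chr2", "chr2", "chr2"],
            [10_000, 20_000, 10_000, 20_000, 30_000],
            [0.01] * 5,
            [-2.0] * 5,
        )
        regions, _ = candidate_regions(t)
        assert [r.chrom for r in regions] == ["chr2"]
        assert regions[0].population_favored == "B"

    def test_tie_reports_both(self):
        t = fake_scan_table(
            ["chr1"] * 4,
            [10_000, 20_000, 30_000, 40_000],
            [0.01] * 4,
            [2.0, 2.0, -2.0, -2.0],
        )
        regions, _ = candidate_regions(t)
        assert regions[0].population_favored == "A|B"

    def test_bed_is_zero_based_half_open(self):
        t = fake_scan_table(
            ["chr1"] * 3, [10_000, 20_000, 30_000], [0.01] * 3, [2.0] * 3
        )
        regions, _ = candidate_regions(t)
        bed = regions_to_bed(regions)
        assert bed.loc[0, "start"] == regions[0].start - 1
        assert bed.loc[0, "end"] == regions[0].end
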