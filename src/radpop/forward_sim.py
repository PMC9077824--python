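"""Forward-time Wright-Fisher simulation and synthetic cohort generation.

Two roles:

1. Replicate the migration-rate inference design: two populations (sizes N1,
   N2, equal sexes, random mating with distinct male/female parent pools),
   non-overlapping generations, biallelic loci with free recombination and a
   symmetric two-state flip mutation model, maximal initial variability
   (alleles assigned at random), run for a fixed number of generations; the
   multi-locus Weir-Cockerham FST of the final generation is compared to an
   observed interval across a grid of migration rates.

2. Generate synthetic phased cohorts — optionally containing a
   chromosomal-inversion system — with complete ground truth, standing in for
   a real RAD-capture data set in every downstream test.

The Wright-Fisher engine stores haplotypes bit-packed in uint64 words; with
free recombination a gamete is formed by choosing each locus independently
from the parent's two haplotypes, which is exactly a random 64-bit mask per
word. A full-scale run (4,850 diploids, 200 loci, 930 generations) takes a
few seconds on one CPU.

Simulations are fully seeded and replayable: the same seed gives
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .inversion_call import GenomicRegion
from .popgen_stats import wc_fst
from .variant_io import (
    MISSING,
    UNASSIGNED,
    GenotypeMatrix,
    HaplotypeSet,
    PopulationMap,
    VariantTable,
    write_metadata,
    write_vcf,
)

__all__ = [
    "SimParams",
    "InversionParams",
    "SimTruth",
    "Cohort",
    "simulate_wf",
    "select_migration_rate",
    "simulate_inversion_cohort",
    "simulate_null_cohort",
    "MIGRATION_RATE_GRID",
]

#: The 10-rate migration grid explored by the demographic inference.
MIGRATION_RATE_GRID = (0, 0.0001, 0.001, 0.002, 0.003, 0.004, 0.005, 0.01, 0.02, 0.03)


@dataclass
class SimParams:
    """Wright-Fisher simulation parameters.

    ``migration`` is a per-generation, per-individual probability of moving
    to another population (destination uniform among the others); a full
    matrix is accepted where entry [i, j] is the probability of moving from
    population i to j.
    """

    pop_sizes: tuple[int, ...] = (4500, 350)
    migration: float | np.ndarray = 0.001
    n_loci: int = 1000
    mu: float = 3.28e-9  # two-state flip probability per transmitted allele
    generations: int = 930
    init: str = "MAXIMAL_VARIABILITY"  # or FIXED_FREQS
    init_freq: float = 0.5  # used with FIXED_FREQS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if np.isscalar(self.migration):
            if not 0 <= float(self.migration) < 1:
                raise ValueError("migration rate must be in [0, 1)")
        else:
            m = np.asarray(self.migration, dtype=float)
            out = m.sum(axis=1) - np.diag(m)
            if np.any(out >= 1):
                raise ValueError("summed out-migration must be < 1 per population")


@dataclass
class InversionParams:
    """Synthetic inversion system for cohort generation.

    Two arrangement-specific haplotype pools for the region SNPs are diverged
    by haploid drift to ``target_fst``; the arrangement itself is transmitted
    as a single Mendelian locus (no recombination between region SNPs in
    arrangement heterozygotes — region haplotypes are drawn whole from the
    carrier arrangement's pool). ``s`` is a selection coefficient favouring
    arrangement B in ``selected_pop`` via fitness-weighted karyotype
    sampling.
    """

    region: GenomicRegion = field(
        default_factory=lambda: GenomicRegion("chr8", 15_260_000, 15_900_000)
    )
    n_region_snps: int = 58
    arrangement_freqs: tuple[float, ...] = (0.95, 0.05)  # freq of arrangement B? per pop
    target_fst: float = 0.8
    s: float = 0.0
    selected_pop: str | None = None
    pool_size: int = 200  # haplotypes per arrangement pool during drift
    max_drift_generations: int = 20_000

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("s must be >= 0")
        for f in self.arrangement_freqs:
            if not 0 <= f <= 1:
                raise ValueError("arrangement frequencies must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth emitted with every simulation."""

    population: list[str]  # natal population per individual
    migrant: list[bool]  # moved populations in the final generation
    admixed: list[bool]
    arrangement_dosage: list[int] | None  # 0/1/2 copies of arrangement B
    selected_loci: list[str]
    paralog_loci: list[str]
    seed: int
    params: dict

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


@dataclass
class Cohort:
    gm: GenotypeMatrix
    haps: HaplotypeSet | None
    pm: PopulationMap
    truth: SimTruth


# ---------------------------------------------------------------------------
# Bit-packed Wright-Fisher engine
# ---------------------------------------------------------------------------


def _rand_words(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.integers(0, 2**64, size=shape, dtype=np.uint64)


def _unpack_bits(H: np.ndarray, n_loci: int) -> np.ndarray:
    """(N, n_words) uint64 -> (N, n_loci) uint8, locus l = word l//64, bit l%64."""
    N, n_words = H.shape
    as_bytes = H.view(np.uint8).reshape(N, n_words * 8)
    bits = np.unpackbits(as_bytes, axis=1, bitorder="little")
    return bits[:, :n_loci]


def simulate_wf(params: SimParams) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Run a seeded Wright-Fisher simulation; return final-generation genotypes.

    Migration happens before reproduction each generation. Every offspring
    draws a mother (from females) and a father (from males) uniformly from
    its natal population's post-migration residents; each transmitted allele
    derives from either parental haplotype independently per locus (free
    recombination) and flips state with probability mu. Population sizes and
    the equal sex ratio are constant.
    """
    rng = np.random.default_rng(params.seed)
    sizes = np.asarray(params.pop_sizes, dtype=int)
    npop = len(sizes)
    N = int(sizes.sum())
    L = params.n_loci
    n_words = (L + 63) // 64
    pop = np.repeat(np.arange(npop), sizes)
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    # equal sexes per population (0 = female, 1 = male), shuffled
    sex = np.empty(N, dtype=np.int8)
    for k in range(npop):
        s = np.zeros(sizes[k], dtype=np.int8)
        s[sizes[k] // 2 :] = 1
        rng.shuffle(s)
        sex[offsets[k] : offsets[k + 1]] = s

    if params.init == "MAXIMAL_VARIABILITY":
        H0 = _rand_words(rng, (N, n_words))
        H1 = _rand_words(rng, (N, n_words))
    elif params.init == "FIXED_FREQS":
        bits0 = rng.random((N, n_words * 64)) < params.init_freq
        bits1 = rng.random((N, n_words * 64)) < params.init_freq
        H0 = np.packbits(bits0, axis=1, bitorder="little").view(np.uint64).reshape(N, n_words)
        H1 = np.packbits(bits1, axis=1, bitorder="little").view(np.uint64).reshape(N, n_words)
    else:
        raise ValueError(f"unknown init {params.init!r}")

    if np.isscalar(params.migration):
        m_scalar = float(params.migration)
        mig_matrix = None
    else:
        m_scalar = None
        mig_matrix = np.asarray(params.migration, dtype=float)

    migrant_flag = np.zeros(N, dtype=bool)
    tail_mask = np.uint64((1 << (L - 64 * (n_words - 1))) - 1) if L % 64 else np.uint64(
        2**64 - 1
    )

    for gen in range(params.generations):
        # --- migration ---
        cur = pop.copy()
        if npop > 1:
            if m_scalar is not None and m_scalar > 0:
                moves = rng.random(N) < m_scalar
            elif mig_matrix is not None:
                out_rate = mig_matrix.sum(axis=1) - np.diag(mig_matrix)
                moves = rng.random(N) < out_rate[pop]
            else:
                moves = np.zeros(N, dtype=bool)
            if moves.any():
                shift = rng.integers(1, npop, size=int(moves.sum()))
                cur[moves] = (cur[moves] + shift) % npop
            migrant_flag = moves
        # --- reproduction ---
        mothers = np.empty(N, dtype=np.int64)
        fathers = np.empty(N, dtype=np.int64)
        for k in range(npop):
            fem = np.flatnonzero((cur == k) & (sex == 0))
            mal = np.flatnonzero((cur == k) & (sex == 1))
            if len(fem) == 0 or len(mal) == 0:
                raise RuntimeError(
                    f"population {k} lost all {'females' if len(fem) == 0 else 'males'} "
                    f"at generation {gen}"
                )
            sl = slice(offsets[k], offsets[k + 1])
            mothers[sl] = fem[rng.integers(0, len(fem), sizes[k])]
            fathers[sl] = mal[rng.integers(0, len(mal), sizes[k])]

        rA = _rand_words(rng, (N, n_words))
        rB = _rand_words(rng, (N, n_words))
        newH0 = (H0[mothers] & rA) | (H1[mothers] & ~rA)
        newH1 = (H0[fathers] & rB) | (H1[fathers] & ~rB)

        # --- mutation: rare symmetric flips ---
        if params.mu > 0:
            n_mut = rng.binomial(2 * N * L, params.mu)
            for _ in range(n_mut):
                ind = rng.integers(0, N)
                locus = int(rng.integers(0, L))
                word, bit = locus // 64, np.uint64(1) << np.uint64(locus % 64)
                if rng.integers(0, 2) == 0:
                    newH0[ind, word] ^= bit
                else:
                    newH1[ind, word] ^= bit

        H0, H1 = newH0, newH1
        # offspring sexes: equal split per population, shuffled
        for k in range(npop):
            s = np.zeros(sizes[k], dtype=np.int8)
            s[sizes[k] // 2 :] = 1
            rng.shuffle(s)
            sex[offsets[k] : offsets[k + 1]] = s

    H0[:, -1] &= tail_mask
    H1[:, -1] &= tail_mask
    dos = (_unpack_bits(H0, L) + _unpack_bits(H1, L)).astype(np.int8)

    variants = VariantTable(
        np.array([f"chr{l + 1}" for l in range(L)], dtype=object),
        np.ones(L, dtype=np.int64),
        np.array(["A"] * L, dtype=object),
        np.array(["T"] * L, dtype=object),
        np.array([f"locus_{l}" for l in range(L)], dtype=object),
    )
    pop_names = [f"pop{k + 1}" for k in range(npop)]
    samples = [f"{pop_names[pop[i]]}_ind{i}" for i in range(N)]
    gm = GenotypeMatrix(dos, variants, samples)
    pm = PopulationMap(
        {s: pop_names[pop[i]] for i, s in enumerate(samples)},
        {s: pop_names[pop[i]] for i, s in enumerate(samples)},
    )
    truth = SimTruth(
        population=[pop_names[k] for k in pop],
        migrant=migrant_flag.tolist(),
        admixed=[False] * N,
        arrangement_dosage=None,
        selected_loci=[],
        paralog_loci=[],
        seed=params.seed,
        params={**asdict(params), "migration": np.asarray(params.migration).tolist()},
    )
    return gm, pm, truth


def select_migration_rate(
    observed_fst: tuple[float, float],
    rates: tuple[float, ...] = MIGRATION_RATE_GRID,
    reps: int = 5,
    params: SimParams | None = None,
) -> tuple[float, pd.DataFrame]:
    """Grid search: which migration rate reproduces the observed FST interval.

    Runs ``reps`` seeded replicates per rate, takes the replicate-mean
    multi-locus Weir-Cockerham FST between the two populations, and returns
    the rate whose mean falls inside ``observed_fst``. If none (or several)
    do, the rate whose mean is closest to the interval midpoint is returned;
    all per-rate means are reported either way.
    """
    if reps < 3:
        raise ValueError("need at least 3 replicates per rate")
    if params is None:
        params = SimParams()
    lo, hi = observed_fst
    mid = (lo + hi) / 2
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(len(rates) * reps)
    rows = []
    for i, rate in enumerate(rates):
        vals = []
        for r in range(reps):
            seed_r = int(children[i * reps + r].generate_state(1)[0] % (2**31))
            p = SimParams(
                pop_sizes=params.pop_sizes,
                migration=rate,
                n_loci=params.n_loci,
                mu=params.mu,
                generations=params.generations,
                init=params.init,
                init_freq=params.init_freq,
                seed=seed_r,
            )
            gm, pm, _ = simulate_wf(p)
            est = wc_fst(gm, pm, n_boot=0)
            vals.append(est.point)
        rows.append(
            {
                "rate": rate,
                "mean_fst": float(np.mean(vals)),
                "sd_fst": float(np.std(vals, ddof=1)),
                "n_reps": reps,
            }
        )
    table = pd.DataFrame(rows)
    inside = table[(table["mean_fst"] >= lo) & (table["mean_fst"] <= hi)]
    if len(inside) == 1:
        best = float(inside["rate"].iloc[0])
    else:
        cand = inside if len(inside) > 1 else table
        best = float(cand.loc[(cand["mean_fst"] - mid).abs().idxmin(), "rate"])
    return best, table


# ---------------------------------------------------------------------------
# Synthetic cohort generation
# ---------------------------------------------------------------------------


def _drift_pools(
    n_snps: int,
    target_fst: float,
    pool_size: int,
    max_generations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Diverge two haploid pools from common founder freqs until Nei FST >= target.

    Returns the two pools' allele-frequency vectors. Raises if the target is
    not reached within ``max_generations`` (reporting the achieved value).
    """
    p0 = rng.uniform(0.1, 0.9, size=n_snps)
    pa = p0.copy()
    pb = p0.copy()

    def fst(pa, pb):
        hs = (pa * (1 - pa) + pb * (1 - pb))  # proportional to within
        pbar = (pa + pb) / 2
        ht = 2 * pbar * (1 - pbar)
        num = (ht - hs).sum()
        den = ht.sum()
        return num / den if den > 0 else 1.0

    achieved = fst(pa, pb)
    for _ in range(max_generations):
        if achieved >= target_fst:
            return pa, pb
        pa = rng.binomial(pool_size, pa) / pool_size
        pb = rng.binomial(pool_size, pb) / pool_size
        achieved = fst(pa, pb)
    raise RuntimeError(
        f"target FST {target_fst} not reached in {max_generations} generations "
        f"(achieved {achieved:.3f})"
    )


def _balding_nichols(
    p0: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    if F <= 0:
        return p0.copy()
    a = p0 * (1 - F) / F
    b = (1 - p0) * (1 - F) / F
    return rng.beta(np.maximum(a, 1e-6), np.maximum(b, 1e-6))


def _layout_variants(
    inv: InversionParams | None,
    background_chroms: int,
    chrom_length: int,
    snp_spacing: int,
) -> VariantTable:
    chroms, poss = [], []
    for c in range(1, background_chroms + 1):
        name = f"chr{c}"
        for p in range(snp_spacing, chrom_length + 1, snp_spacing):
            chroms.append(name)
            poss.append(p)
    if inv is not None:
        r = inv.region
        flank = 360_000
        lo = max(1, r.start - flank)
        hi = r.end + flank
        bg = [
            p
            for p in range(lo, hi + 1, snp_spacing)
            if p < r.start or p > r.end
        ]
        region = np.linspace(r.start, r.end, inv.n_region_snps).round().astype(int)
        region = np.unique(region)
        allpos = sorted(set(bg) | set(region.tolist()))
        for p in allpos:
            chroms.append(r.chrom)
            poss.append(p)
    n = len(poss)
    return VariantTable(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(["A"] * n, dtype=object),
        np.array(["T"] * n, dtype=object),
        np.array([f"{c}_{p}" for c, p in zip(chroms, poss)], dtype=object),
    )


def simulate_inversion_cohort(
    params: SimParams | None = None,
    inv: InversionParams | None = None,
    missingness: float = 0.05,
    depth_mean: float = 20.0,
    n_admixed: int = 0,
    background_fst: float = 0.02,
    background_chroms: int = 4,
    chrom_length: int = 1_000_000,
    snp_spacing: int = 5_000,
    n_paralogs: int = 0,
    out_dir: str | None = None,
) -> Cohort:
    """Generate a phased synthetic cohort carrying an inversion system.

    Background SNPs sit every ``snp_spacing`` bp on ``background_chroms``
    chromosomes plus the inversion chromosome, with per-population allele
    frequencies drawn from a Balding-Nichols model at ``background_fst``.
    Region SNPs are drawn whole-haplotype from the carrier arrangement's pool
    (recombination between region SNPs suppressed in heterokaryotypes).
    Genotype depths are Poisson(``depth_mean``), allele-balanced for true
    heterozygotes; ``missingness`` is applied after truth capture. Optional
    paralog artifacts (all carriers heterozygous, 2:1 read ratio) exercise
    the HDPlot filter.

    With ``out_dir`` set, writes cohort.vcf, metadata.tsv and truth.json.
    """
    if params is None:
        params = SimParams(pop_sizes=(75, 75), migration=0.0)
    rng = np.random.default_rng(params.seed)
    sizes = list(params.pop_sizes)
    npop = len(sizes)
    pop_names = [f"pop{k + 1}" for k in range(npop)]

    variants = _layout_variants(inv, background_chroms, chrom_length, snp_spacing)
    n_snps = len(variants)
    if inv is not None:
        region_idx = np.flatnonzero(
            variants.region_mask(inv.region.chrom, inv.region.start, inv.region.end)
        )
        if len(region_idx) < 3:
            raise ValueError("inversion region must contain >= 3 SNPs")
        if len(inv.arrangement_freqs) != npop:
            raise ValueError("need one arrangement frequency per population")
        pool_a, pool_b = _drift_pools(
            len(region_idx), inv.target_fst, inv.pool_size, inv.max_drift_generations, rng
        )
    else:
        region_idx = np.array([], dtype=int)

    bg_idx = np.setdiff1d(np.arange(n_snps), region_idx)
    p0 = rng.uniform(0.05, 0.95, size=len(bg_idx))
    bg_freqs = [_balding_nichols(p0, background_fst, rng) for _ in range(npop)]

    # individuals: per population, then admixed (between first two populations)
    N = sum(sizes) + n_admixed
    samples, site, popl = [], {}, {}
    origin, admixed_flags = [], []
    hap_pop = np.empty((N, 2), dtype=int)  # source population of each haplotype
    i = 0
    for k in range(npop):
        for _ in range(sizes[k]):
            s = f"{pop_names[k]}_ind{i}"
            samples.append(s)
            site[s] = pop_names[k]
            popl[s] = pop_names[k]
            origin.append(pop_names[k])
            admixed_flags.append(False)
            hap_pop[i] = (k, k)
            i += 1
    for _ in range(n_admixed):
        s = f"admixed_ind{i}"
        samples.append(s)
        site[s] = "admixed_site"
        popl[s] = UNASSIGNED
        origin.append("admixed")
        admixed_flags.append(True)
        hap_pop[i] = (0, 1)
        i += 1

    # Q matrix: near-pure members; admixed ~0.5/0.5 over the first two clusters
    qrows = np.zeros((N, npop))
    for j in range(N):
        if admixed_flags[j]:
            a = rng.uniform(0.45, 0.55)
            qrows[j, 0], qrows[j, 1] = a, 1 - a
        else:
            k = hap_pop[j, 0]
            own = rng.uniform(0.90, 0.99)
            rest = rng.dirichlet(np.ones(npop - 1)) * (1 - own)
            qrows[j] = np.insert(rest, k, own)
    q = pd.DataFrame(qrows, index=samples, columns=pop_names)
    pm = PopulationMap(site, popl, q)

    # haplotypes
    H = np.zeros((2 * N, n_snps), dtype=np.uint8)
    for h in range(2):
        src = hap_pop[:, h]
        for k in range(npop):
            rows = np.flatnonzero(src == k)
            if len(rows) == 0:
                continue
            H[np.ix_(2 * rows + h, bg_idx)] = (
                rng.random((len(rows), len(bg_idx))) < bg_freqs[k]
            ).astype(np.uint8)

    arrangement_dosage = None
    if inv is not None:
        arr = np.zeros((N, 2), dtype=np.uint8)  # 1 = arrangement B per haplotype
        for j in range(N):
            for h in range(2):
                f = inv.arrangement_freqs[hap_pop[j, h]]
                arr[j, h] = rng.random() < f
        if inv.s > 0 and inv.selected_pop is not None:
            # fitness-weighted rejection of karyotypes in the selected population
            w = np.array([1.0, 1.0 + inv.s / 2, 1.0 + inv.s])
            for j in range(N):
                if origin[j] != inv.selected_pop:
                    continue
                while rng.random() > w[arr[j].sum()] / w.max():
                    for h in range(2):
                        f = inv.arrangement_freqs[hap_pop[j, h]]
                        arr[j, h] = rng.random() < f
        arrangement_dosage = arr.sum(axis=1).astype(int).tolist()
        for j in range(N):
            for h in range(2):
                pool = pool_b if arr[j, h] else pool_a
                H[2 * j + h, region_idx] = (
                    rng.random(len(region_idx)) < pool
                ).astype(np.uint8)

    paralog_ids: list[str] = []
    dos = (H[0::2] + H[1::2]).astype(np.int8)
    haps = HaplotypeSet(H, variants, samples)

    # depths: Poisson totals, balanced for hets; paralogs get a 2:1 skew
    tot = np.maximum(rng.poisson(depth_mean, size=dos.shape), 1)
    ref = np.where(dos == 0, tot, 0)
    het_mask = dos == 1
    ref = ref + np.where(het_mask, rng.binomial(tot, 0.5), 0)
    if n_paralogs > 0:
        paralog_cols = rng.choice(bg_idx, size=n_paralogs, replace=False)
        for c in paralog_cols:
            dos[:, c] = 1  # collapsed duplicate: every carrier heterozygous
            tot[:, c] = np.maximum(rng.poisson(depth_mean * 1.5, size=N), 3)
            ref[:, c] = rng.binomial(tot[:, c], 2.0 / 3.0)
            paralog_ids.append(str(variants.locus_id[c]))
    depths = np.stack([ref, tot - ref], axis=2).astype(np.int32)

    truth = SimTruth(
        population=origin,
        migrant=[False] * N,
        admixed=admixed_flags,
        arrangement_dosage=arrangement_dosage,
        selected_loci=[],
        paralog_loci=paralog_ids,
        seed=params.seed,
        params={
            "pop_sizes": sizes,
            "n_admixed": n_admixed,
            "missingness": missingness,
            "depth_mean": depth_mean,
            "background_fst": background_fst,
            "inversion": None if inv is None else asdict(inv),
        },
    )

    # missingness applied after truth capture
    if missingness > 0:
        miss = rng.random(dos.shape) < missingness
        dos = dos.copy()
        dos[miss] = MISSING
        depths = depths.copy()
        depths[miss] = 0
        # paralog artifacts break phasing anyway; keep haplotypes only when
        # the exported matrix is complete
        gm = GenotypeMatrix(dos, variants, samples, depths)
        haps_out = None if (miss.any() or n_paralogs > 0) else haps
    else:
        gm = GenotypeMatrix(dos, variants, samples, depths)
        haps_out = haps if n_paralogs == 0 else None

    cohort = Cohort(gm, haps_out if haps_out is not None else haps, pm, truth)
    # the phased HaplotypeSet kept on the cohort is the pre-missingness truth;
    # the exported VCF carries the post-missingness genotype calls
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if haps_out is not None:
            write_vcf(str(out / "cohort.vcf"), gm, haps_out)
        else:
            write_vcf(str(out / "cohort.vcf"), gm)
        write_metadata(str(out / "metadata.tsv"), pm)
        truth.to_json(str(out / "truth.json"))
    return cohort


def simulate_null_cohort(
    n_per_pop: tuple[int, int] = (75, 75),
    n_snps: int = 400,
    snp_spacing: int = 5_000,
    seed: int = 0,
) -> Cohort:
    """Two labelled cohorts drawn from one shared panmictic pool (no structure).

    A null fixture for selection scans and permutation checks: every SNP's
    allele frequency is identical in both populations by construction.
    """
    params = SimParams(pop_sizes=tuple(n_per_pop), migration=0.0, seed=seed)
    n_chroms = max(2, n_snps * snp_spacing // 1_000_000)
    per_chrom = n_snps // n_chroms
    cohort = simulate_inversion_cohort(
        params,
        inv=None,
        missingness=0.0,
        depth_mean=20.0,
        background_fst=0.0,
        background_chroms=n_chroms,
        chrom_length=per_chrom * snp_spacing,
        snp_spacing=snp_spacing,
    )
    return cohort
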