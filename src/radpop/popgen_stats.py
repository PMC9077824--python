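"""Differentiation and diversity estimators.

Implements the Weir & Cockerham (1984) variance-components FST with percentile
bootstrap CIs over loci, Nei-style basic diversity statistics with the
small-sample gene-diversity correction (Ho, Hs, Ht, Fis, and the
sample-size-corrected F'ST), the population-specific differentiation
coefficient beta_WT of Weir & Goudet (2017) in its allele-matching
formulation, a method-of-moments IBD/kinship estimator (PI_HAT), and absolute
allele-frequency differences between two populations.

Multi-locus combining is ratio-of-sums throughout (not mean of per-locus
ratios), matching the cited estimators. Negative FST estimates are reported
as computed, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "FstEstimate",
    "DiversityTable",
    "BetaWTEstimate",
    "wc_fst",
    "wc_components",
    "basic_stats",
    "beta_wt",
    "kinship_mom",
    "allele_freq_diff",
]


@dataclass(frozen=True)
class FstEstimate:
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_loci: int


@dataclass(frozen=True)
class DiversityTable:
    per_pop: pd.DataFrame  # index pop, columns Ho, Hs, Fis
    ho_mean: float
    hs_mean: float
    ht: float
    dst: float
    fst_nei: float
    dstp: float
    htp: float
    fstp: float
    fis: float
    fis_ci: tuple[float, float]


@dataclass(frozen=True)
class BetaWTEstimate:
    per_pop: pd.DataFrame  # index pop, columns beta_wt, ci_low, ci_high
    n_loci: int


def _pop_counts(
    gm: GenotypeMatrix, pm: PopulationMap, pops: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per population x locus: sample size n_i, alt freq p_i, het freq h_i.

    Loci where a population has no genotyped individuals get n=0 and NaN
    frequencies.
    """
    r = len(pops)
    L = gm.n_snps
    n = np.zeros((r, L))
    p = np.full((r, L), np.nan)
    h = np.full((r, L), np.nan)
    for k, pop in enumerate(pops):
        idx = pm.members(pop, gm.samples)
        if len(idx) == 0:
            raise ValueError(f"population {pop!r} has no individuals in the matrix")
        sub = gm.values[idx]
        nm = sub != MISSING
        cnt = nm.sum(axis=0)
        n[k] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(nm, sub, 0).sum(axis=0) / (2.0 * cnt)
            h[k] = np.where(nm & (sub == 1), 1, 0).sum(axis=0) / cnt
    return n, p, h


def wc_components(
    gm: GenotypeMatrix, pm: PopulationMap, pops: list[str]
) -> pd.DataFrame:
    """Per-locus Weir & Cockerham variance components a (among populations),
    b (among individuals within populations), c (within individuals).

    Loci unusable for the estimator (fewer than 2 populations with >= 2
    genotyped individuals, or monomorphic across the pooled sample) carry NaN.
    """
    n, p, h = _pop_counts(gm, pm, pops)
    r = len(pops)
    usable = (n >= 2).sum(axis=0) >= 2
    nbar = n.sum(axis=0) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    poly = (pbar > 0) & (pbar < 1)
    ok = usable & poly & np.isfinite(a)
    a = np.where(ok, a, np.nan)
    b = np.where(ok, b, np.nan)
    c = np.where(ok, c, np.nan)
    return pd.DataFrame(
        {"locus_id": gm.variants.locus_id, "a": a, "b": b, "c": c}
    )


def _ratio_of_sums(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    denom = np.nansum(a + b + c)
    if denom == 0 or not np.isfinite(denom):
        return np.nan
    return float(np.nansum(a) / denom)


def wc_fst(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pops: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> FstEstimate:
    """Multi-locus Weir & Cockerham FST, ratio of sums, with a percentile
    bootstrap over loci (95% level)."""
    if pops is None:
        pops = pm.populations()
    if len(pops) < 2:
        raise ValueError("wc_fst needs at least two populations")
    comp = wc_components(gm, pm, pops)
    a = comp["a"].to_numpy()
    b = comp["b"].to_numpy()
    c = comp["c"].to_numpy()
    usable = np.isfinite(a)
    if not usable.any():
        raise ValueError("all loci monomorphic or unusable; FST undefined")
    point = _ratio_of_sums(a, b, c)
    lo = hi = point
    if n_boot >= 1:
        rng = np.random.default_rng(seed)
        ui = np.flatnonzero(usable)
        reps = np.empty(n_boot)
        for t in range(n_boot):
            pick = rng.choice(ui, size=len(ui), replace=True)
            reps[t] = _ratio_of_sums(a[pick], b[pick], c[pick])
        lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    return FstEstimate(point, float(lo), float(hi), n_boot, int(usable.sum()))


def basic_stats(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    n_boot: int = 1000,
    seed: int = 0,
) -> DiversityTable:
    """Nei-style diversity statistics with small-sample corrections.

    Per locus and population (n genotyped individuals):
    ``Ho`` = heterozygote proportion; ``Hs = n/(n-1) * (1 - sum p^2 - Ho/(2n))``.
    Across ``np`` populations with unweighted mean allele frequencies and
    harmonic-mean sample size ``n_h``:
    ``Ht = 1 - sum(pbar^2) + Hs_mean/(n_h*np) - Ho_mean/(2*n_h*np)``,
    ``Dst = Ht - Hs_mean``, ``Dstp = np/(np-1)*Dst``, ``Htp = Hs_mean + Dstp``,
    ``Fstp = Dstp/Htp`` (the sample-size-corrected F'ST),
    ``Fis = 1 - Ho_mean/Hs_mean``. Statistics are averaged over loci; the
    Fis CI is a percentile bootstrap over loci.

    Populations with fewer than 2 genotyped individuals at a locus are
    skipped for that locus.
    """
    pops = pm.populations()
    if not pops:
        raise ValueError("basic_stats needs at least one assigned population")
    n, p, h = _pop_counts(gm, pm, pops)
    npop = len(pops)
    valid = n >= 2  # per pop x locus

    with np.errstate(invalid="ignore", divide="ignore"):
        hs = (n / (n - 1)) * (1 - (p**2 + (1 - p) ** 2) - h / (2 * n))
    hs = np.where(valid, hs, np.nan)
    ho = np.where(valid, h, np.nan)
    p_v = np.where(valid, p, np.nan)

    per_pop = pd.DataFrame(
        {
            "Ho": np.nanmean(ho, axis=1),
            "Hs": np.nanmean(hs, axis=1),
        },
        index=pops,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        per_pop["Fis"] = 1 - per_pop["Ho"] / per_pop["Hs"]

    # overall statistics restricted to loci scored in every population
    all_ok = valid.all(axis=0)
    if not all_ok.any():
        raise ValueError("no locus is scored in every population")
    hs_l = hs[:, all_ok].mean(axis=0)
    ho_l = ho[:, all_ok].mean(axis=0)
    pbar = p_v[:, all_ok].mean(axis=0)  # unweighted over pops
    nh = npop / (1.0 / n[:, all_ok]).sum(axis=0)  # harmonic mean sample size
    ht_l = (
        1 - (pbar**2 + (1 - pbar) ** 2) + hs_l / (nh * npop) - ho_l / (2 * nh * npop)
    )
    dst_l = ht_l - hs_l
    if npop > 1:
        dstp_l = npop / (npop - 1) * dst_l
    else:
        dstp_l = np.zeros_like(dst_l)
    htp_l = hs_l + dstp_l

    ho_mean = float(ho_l.mean())
    hs_mean = float(hs_l.mean())
    ht = float(ht_l.mean())
    dst = ht - hs_mean
    dstp = float(dstp_l.mean())
    htp = float(htp_l.mean())
    fst_nei = dst / ht if ht > 0 else np.nan
    fstp = dstp / htp if htp > 0 else 0.0
    fis = 1 - ho_mean / hs_mean if hs_mean > 0 else np.nan

    lo = hi = fis
    if n_boot >= 1:
        rng = np.random.default_rng(seed)
        L = int(all_ok.sum())
        reps = np.empty(n_boot)
        for t in range(n_boot):
            pick = rng.integers(0, L, size=L)
            hsb = ho_l[pick].mean(), hs_l[pick].mean()
            reps[t] = 1 - hsb[0] / hsb[1] if hsb[1] > 0 else np.nan
        lo, hi = np.nanpercentile(reps, [2.5, 97.5])

    return DiversityTable(
        per_pop=per_pop,
        ho_mean=ho_mean,
        hs_mean=hs_mean,
        ht=ht,
        dst=dst,
        fst_nei=fst_nei,
        dstp=dstp,
        htp=htp,
        fstp=fstp,
        fis=fis,
        fis_ci=(float(lo), float(hi)),
    )


def _matching(
    gm: GenotypeMatrix, pm: PopulationMap, pops: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per pop x locus within-population allele matching M_i (pairs of
    distinct alleles) and per-locus mean between-population matching M_B."""
    r = len(pops)
    L = gm.n_snps
    Mw = np.full((r, L), np.nan)
    p = np.full((r, L), np.nan)
    for k, pop in enumerate(pops):
        idx = pm.members(pop, gm.samples)
        sub = gm.values[idx]
        nm = sub != MISSING
        cnt2 = 2.0 * nm.sum(axis=0)  # allele count
        x = np.where(nm, sub, 0).sum(axis=0).astype(np.float64)  # alt alleles
        y = cnt2 - x
        with np.errstate(invalid="ignore", divide="ignore"):
            Mw[k] = (x * (x - 1) + y * (y - 1)) / (cnt2 * (cnt2 - 1))
            p[k] = x / cnt2
    # between-population matching: mean over unordered pairs of p_i p_j + q_i q_j
    Mb = np.zeros(L)
    npair = 0
    for i in range(r):
        for j in range(i + 1, r):
            Mb += p[i] * p[j] + (1 - p[i]) * (1 - p[j])
            npair += 1
    Mb /= npair
    return Mw, Mb


def beta_wt(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pops: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> BetaWTEstimate:
    """Population-specific differentiation beta_WT (allele matching).

    ``beta_i = (M_i - M_B) / (1 - M_B)`` per locus, combined over loci as a
    ratio of sums; percentile bootstrap resamples loci only.
    """
    if pops is None:
        pops = pm.populations()
    if len(pops) < 2:
        raise ValueError("beta_wt needs at least two populations")
    Mw, Mb = _matching(gm, pm, pops)
    ok = np.isfinite(Mb) & np.isfinite(Mw).all(axis=0) & (1 - Mb > 0)
    if not ok.any():
        raise ValueError("1 - M_B is zero everywhere; beta_WT undefined")
    num = Mw[:, ok] - Mb[ok]
    den = 1 - Mb[ok]
    point = num.sum(axis=1) / den.sum()
    rng = np.random.default_rng(seed)
    L = int(ok.sum())
    lo = np.full(len(pops), np.nan)
    hi = np.full(len(pops), np.nan)
    if n_boot >= 1:
        reps = np.empty((n_boot, len(pops)))
        for t in range(n_boot):
            pick = rng.integers(0, L, size=L)
            reps[t] = num[:, pick].sum(axis=1) / den[pick].sum()
        lo, hi = np.nanpercentile(reps, [2.5, 97.5], axis=0)
    df = pd.DataFrame(
        {"beta_wt": point, "ci_low": lo, "ci_high": hi}, index=pops
    )
    return BetaWTEstimate(df, L)


def kinship_mom(gm: GenotypeMatrix, min_overlap: int = 100) -> pd.DataFrame:
    """Method-of-moments IBD estimation (PI_HAT) for every individual pair.

    Observed IBS0/IBS1/IBS2 counts are combined with expected IBS-given-IBD
    probabilities computed from sample allele frequencies using factorial-
    moment small-sample corrections (products of distinct allele draws).
    P(IBD=0,1,2) are solved sequentially, truncated to [0,1] and
    renormalised; ``PI_HAT = P(IBD=2) + P(IBD=1)/2``.

    Pairs with fewer than ``min_overlap`` shared non-missing SNPs are flagged
    ``unreliable``. Intended for LD-pruned input.
    """
    G = gm.values
    n_ind, L = G.shape
    nm = G != MISSING
    cnt = nm.sum(axis=0).astype(np.float64)
    T = 2.0 * cnt  # total alleles
    X = np.where(nm, G, 0).sum(axis=0).astype(np.float64)  # alt allele count
    Y = T - X

    ok = (T >= 4) & (X >= 1) & (Y >= 1)  # polymorphic with enough alleles

    def fm(draws: list[tuple[int, np.ndarray]]) -> np.ndarray:
        """Unbiased estimate of a product of distinct allele-draw probabilities.

        E.g. p^2 q^2 is estimated by X(X-1)Y(Y-1) / (T(T-1)(T-2)(T-3)).
        """
        num = np.ones_like(T)
        den = np.ones_like(T)
        taken: dict[int, int] = {}
        tot = 0
        for arr_id, arr in draws:
            k = taken.get(arr_id, 0)
            num = num * (arr - k)
            taken[arr_id] = k + 1
            den = den * (T - tot)
            tot += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, 0.0)

    # expected per-SNP IBS|IBD probabilities with factorial-moment corrections
    XX, YY = (0, X), (1, Y)
    e0_ibd0 = 2 * fm([XX, XX, YY, YY])
    e1_ibd0 = 4 * fm([XX, XX, XX, YY]) + 4 * fm([XX, YY, YY, YY])
    e2_ibd0 = fm([XX, XX, XX, XX]) + fm([YY, YY, YY, YY]) + 4 * fm([XX, XX, YY, YY])
    e1_ibd1 = 2 * fm([XX, XX, YY]) + 2 * fm([XX, YY, YY])
    e2_ibd1 = fm([XX, XX, XX]) + fm([YY, YY, YY]) + fm([XX, XX, YY]) + fm([XX, YY, YY])

    for arr in (e0_ibd0, e1_ibd0, e2_ibd0, e1_ibd1, e2_ibd1):
        arr[~ok] = 0.0
    w = ok.astype(np.float64)

    rows = []
    Gf = G.astype(np.int16)
    for i in range(n_ind):
        for j in range(i + 1, n_ind):
            both = nm[i] & nm[j] & ok
            d = np.abs(Gf[i] - Gf[j])
            o0 = int(((d == 2) & both).sum())
            o2_raw = (d == 0) & both
            o1 = int(((d == 1) & both).sum())
            o2 = int(o2_raw.sum())
            # expectations restricted to SNPs genotyped in both individuals
            E00 = float(e0_ibd0[both].sum())
            E10 = float(e1_ibd0[both].sum())
            E20 = float(e2_ibd0[both].sum())
            E11 = float(e1_ibd1[both].sum())
            E21 = float(e2_ibd1[both].sum())
            n_obs = int(both.sum())
            if n_obs == 0 or E00 <= 0 or E11 <= 0:
                z0, z1, z2 = np.nan, np.nan, np.nan
            else:
                z0 = o0 / E00
                z1 = (o1 - z0 * E10) / E11
                # E[IBS2 count | IBD2] equals the overlap size (prob 1 per SNP)
                z2 = (o2 - z0 * E20 - z1 * E21) / n_obs
                z = np.clip([z0, z1, z2], 0.0, 1.0)
                s = z.sum()
                z0, z1, z2 = (z / s) if s > 0 else (np.nan, np.nan, np.nan)
            pi_hat = z2 + z1 / 2 if np.isfinite(z2) else np.nan
            rows.append(
                {
                    "id1": gm.samples[i],
                    "id2": gm.samples[j],
                    "z0": z0,
                    "z1": z1,
                    "z2": z2,
                    "pi_hat": pi_hat,
                    "n_snps": n_obs,
                    "unreliable": n_obs < min_overlap,
                }
            )
    return pd.DataFrame(rows)


def allele_freq_diff(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pop_a: str,
    pop_b: str,
    orient_pop: str | None = None,
) -> pd.DataFrame:
    """Per-SNP absolute allele-frequency difference |p_A - p_B|.

    Frequencies are taken for the same allele in both populations. When
    ``orient_pop`` is given, the frequency reported is of that population's
    minor allele (defaults to ``pop_a``); the absolute difference is
    orientation-invariant but the signed columns are not.
    """
    if orient_pop is None:
        orient_pop = pop_a
    freqs = {}
    for pop in (pop_a, pop_b, orient_pop):
        idx = pm.members(pop, gm.samples)
        if len(idx) == 0:
            raise ValueError(f"population {pop!r} is empty")
        freqs[pop] = gm.take_individuals(idx).allele_freq()
    flip = freqs[orient_pop] > 0.5  # orient on the orientation population's minor allele
    pa = np.where(flip, 1 - freqs[pop_a], freqs[pop_a])
    pb = np.where(flip, 1 - freqs[pop_b], freqs[pop_b])
    return pd.DataFrame(
        {
            "chrom": gm.variants.chrom,
            "pos": gm.variants.pos,
            "locus_id": gm.variants.locus_id,
            "p_a": pa,
            "p_b": pb,
            "abs_diff": np.abs(pa - pb),
        }
    )
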