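"""Pairwise linkage disequilibrium, LD-decay curve fitting, and LD-based Ne.

The decay curve is the Hill & Weir (1988) expectation for r² as a function of
the population recombination parameter C = rho * distance and the number of
sampled chromosomes n:

    E[r^2](C) = (10 + C) / ((2 + C)(11 + C))
                * [1 + ((3 + C)(12 + 12C + C^2)) / (n (2 + C)(11 + C))]

fitted by nonlinear least squares over observed (distance, r²) pairs. From
the fitted curve the half-decay distance (E[r²] falls to half its fitted
value at d = 0) and the moderate-LD distance (E[r²] <= 0.20) are solved by
bisection to 1-bp resolution.

Effective population size uses the LD method restricted to pairs of SNPs on
different chromosomes, with the Waples (2006) sampling-bias correction for
S >= 30 sampled individuals: E[r²_sample] = 1/S + 3.19/S², and
Ne = (1/3 + sqrt(1/9 - 2.76 r²_drift)) / (2 r²_drift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .variant_io import MISSING, GenotypeMatrix, HaplotypeSet, PopulationMap

__all__ = [
    "LdPairList",
    "DecayFit",
    "NeEstimate",
    "pairwise_r2",
    "hill_weir_expectation",
    "fit_ld_decay",
    "decay_distances",
    "ld_ne",
]


@dataclass(frozen=True)
class LdPairList:
    pairs: pd.DataFrame  # snp_i, snp_j, dist_bp, r2
    report_floor: float = 0.0


@dataclass(frozen=True)
class DecayFit:
    rho: float  # recombination-scale parameter per bp; C = rho * dist
    n: int  # sampled chromosomes
    r2_max: float  # fitted expectation at dist -> 0
    half_decay_bp: float
    moderate_bp: float
    rss: float
    n_pairs: int


@dataclass(frozen=True)
class NeEstimate:
    ne: float  # may be +inf
    ci_low: float
    ci_high: float
    S: float  # harmonic-mean sample size
    n_pairs: int
    mean_r2: float
    expected_sample_r2: float
    r2_drift: float


def _columns(data, scope: str, region=None):
    """Dosage or haplotype value matrix plus variant coordinates."""
    if isinstance(data, HaplotypeSet):
        values = data.values.astype(np.float64)
        missing = np.zeros_like(values, dtype=bool)
    elif isinstance(data, GenotypeMatrix):
        values = data.values.astype(np.float64)
        missing = data.values == MISSING
    else:
        raise TypeError("expected GenotypeMatrix or HaplotypeSet")
    return values, missing, data.variants


def pairwise_r2(
    data,
    scope: str = "within-chrom",
    max_dist_kb: float | None = None,
    report_floor: float = 0.0,
    region: tuple[str, int, int] | None = None,
) -> LdPairList:
    """All-pairs squared correlation of dosage (or haplotype) columns.

    ``scope`` is one of ``within-chrom`` (pairs on the same chromosome, with
    bp distances), ``between-chrom`` (pairs on different chromosomes,
    dist_bp = 0), or ``region`` (pairs within the closed interval ``region``
    = (chrom, start, end)). r² uses individuals non-missing at both SNPs;
    pairs where either SNP is monomorphic in the overlap are skipped. Pairs
    with r² < ``report_floor`` are omitted when the floor is > 0.
    """
    values, missing, variants = _columns(data, scope)
    idx = np.arange(len(variants))
    if scope == "region":
        if region is None:
            raise ValueError("scope='region' requires region=(chrom, start, end)")
        mask = variants.region_mask(*region)
        idx = np.flatnonzero(mask)
    if len(idx) < 2:
        raise ValueError("need at least 2 SNPs in scope")

    chrom = variants.chrom[idx]
    pos = variants.pos[idx]
    sub = values[:, idx]
    submiss = missing[:, idx]

    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []

    if not submiss.any():
        # complete data: one correlation matrix per needed block
        std = sub.std(axis=0)
        poly = std > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (sub - sub.mean(axis=0)) / np.where(poly, std, 1.0)
        C = (Z.T @ Z) / sub.shape[0]
        R2 = C**2
        iu, ju = np.triu_indices(len(idx), k=1)
        ok = poly[iu] & poly[ju]
        same = chrom[iu] == chrom[ju]
        if scope == "between-chrom":
            ok &= ~same
            d = np.zeros(len(iu), dtype=np.int64)
        else:
            ok &= same
            d = np.abs(pos[iu] - pos[ju])
        if max_dist_kb is not None:
            ok &= (d <= max_dist_kb * 1000) | (chrom[iu] != chrom[ju])
        rows_i.append(idx[iu[ok]])
        rows_j.append(idx[ju[ok]])
        dists.append(d[ok])
        r2s.append(R2[iu[ok], ju[ok]])
    else:
        m = len(idx)
        for a in range(m):
            for b in range(a + 1, m):
                same = chrom[a] == chrom[b]
                if scope == "between-chrom" and same:
                    continue
                if scope in ("within-chrom", "region") and not same:
                    continue
                d = abs(int(pos[a] - pos[b])) if same else 0
                if max_dist_kb is not None and same and d > max_dist_kb * 1000:
                    continue
                both = ~submiss[:, a] & ~submiss[:, b]
                if both.sum() < 2:
                    continue
                x, y = sub[both, a], sub[both, b]
                if x.std() == 0 or y.std() == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                rows_i.append(np.array([idx[a]]))
                rows_j.append(np.array([idx[b]]))
                dists.append(np.array([d]))
                r2s.append(np.array([r * r]))

    df = pd.DataFrame(
        {
            "snp_i": np.concatenate(rows_i) if rows_i else np.array([], dtype=int),
            "snp_j": np.concatenate(rows_j) if rows_j else np.array([], dtype=int),
            "dist_bp": np.concatenate(dists) if dists else np.array([], dtype=int),
            "r2": np.concatenate(r2s) if r2s else np.array([]),
        }
    )
    if report_floor > 0:
        df = df[df["r2"] >= report_floor].reset_index(drop=True)
    return LdPairList(df, report_floor)


def hill_weir_expectation(dist_bp: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Expected r² at physical distance ``dist_bp`` for ``n`` sampled chromosomes."""
    C = rho * np.asarray(dist_bp, dtype=np.float64)
    lead = (10 + C) / ((2 + C) * (11 + C))
    corr = 1 + ((3 + C) * (12 + 12 * C + C**2)) / (n * (2 + C) * (11 + C))
    return lead * corr


def fit_ld_decay(
    pairs: LdPairList,
    n: int,
    rho_start: float = 1e-4,
    n_restarts: int = 8,
) -> DecayFit:
    """Least-squares fit of the Hill-Weir expectation to observed (dist, r²).

    The single free parameter rho (per bp) is constrained >= 0. Fitting
    restarts from a log-spaced grid of starting values around ``rho_start``
    and keeps the solution with the lowest residual sum of squares.
    """
    if n < 4:
        raise ValueError("need n >= 4 sampled chromosomes")
    df = pairs.pairs
    d = df["dist_bp"].to_numpy(dtype=np.float64)
    r2 = df["r2"].to_numpy(dtype=np.float64)
    if len(d) < 3 or d.max() == d.min():
        raise ValueError("pairs must span a range of distances")

    starts = rho_start * np.logspace(-3, 3, n_restarts)
    best = None
    for s in starts:
        try:
            popt, _ = optimize.curve_fit(
                lambda x, rho: hill_weir_expectation(x, rho, n),
                d,
                r2,
                p0=[s],
                bounds=(0.0, np.inf),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        resid = r2 - hill_weir_expectation(d, popt[0], n)
        rss = float(resid @ resid)
        if best is None or rss < best[1]:
            best = (float(popt[0]), rss)
    if best is None:
        resid = r2 - hill_weir_expectation(d, rho_start, n)
        raise RuntimeError(
            f"LD decay fit failed to converge; best residual {float(resid @ resid):.4g}"
        )
    rho, rss = best
    r2_max = float(hill_weir_expectation(np.array([0.0]), rho, n)[0])
    fit = DecayFit(rho, n, r2_max, np.nan, np.nan, rss, len(d))
    half, mod = decay_distances(fit)
    return DecayFit(rho, n, r2_max, half, mod, rss, len(d))


def _crossing(fit: DecayFit, level: float, d_hi: float = 1e12) -> float:
    """Smallest distance (1-bp resolution) where the fitted curve <= level."""
    f = lambda d: hill_weir_expectation(np.array([d]), fit.rho, fit.n)[0]
    if f(0.0) <= level:
        return 0.0
    if f(d_hi) > level:
        return np.inf
    lo, hi = 0.0, d_hi
    while hi - lo > 0.5:
        mid = (lo + hi) / 2
        if f(mid) <= level:
            hi = mid
        else:
            lo = mid
    return float(np.ceil(hi))


def decay_distances(fit: DecayFit) -> tuple[float, float]:
    """Half-decay distance and moderate-LD (r² <= 0.20) distance in bp."""
    import warnings

    half = _crossing(fit, fit.r2_max / 2.0)
    if fit.r2_max <= 0.20:
        warnings.warn("fitted r2_max <= 0.20; moderate-LD distance set to 0", stacklevel=2)
        moderate = 0.0
    else:
        moderate = _crossing(fit, 0.20)
    return half, moderate


def ld_ne(
    gm: GenotypeMatrix,
    pm: PopulationMap | None = None,
    pop: str | None = None,
    maf_screen: float = 0.05,
    ci_level: float = 0.95,
) -> NeEstimate:
    """LD-based effective population size from inter-chromosomal SNP pairs.

    Mean r² over all between-chromosome pairs passing the MAF screen is
    weighted by pairwise non-missing sample size; the sampling expectation
    1/S + 3.19/S² (harmonic-mean S >= 30) is subtracted and Ne recovered as
    (1/3 + sqrt(1/9 - 2.76 r²_drift)) / (2 r²_drift); +inf when the drift
    signal is non-positive. The parametric CI treats the drift signal as
    chi-square with an effective number of independent comparisons set to
    the number of loci (the ~L²/2 pairwise comparisons reuse the same L loci
    and S individuals, so counting every pair badly overstates precision).
    """
    if pm is not None and pop is not None:
        idx = pm.members(pop, gm.samples)
        if len(idx) < 10:
            raise ValueError("population must have at least 10 individuals")
        gm = gm.take_individuals(idx)
    if len(pd.unique(gm.variants.chrom)) < 2:
        raise ValueError("ld_ne requires SNPs on at least 2 chromosomes")

    p = gm.allele_freq()
    maf = np.fmin(p, 1 - p)
    keep = np.flatnonzero(maf >= maf_screen)
    if len(keep) < 2:
        raise ValueError("no SNPs pass the MAF screen")
    sub = gm.take_snps(keep)

    values = sub.values.astype(np.float64)
    miss = sub.values == MISSING
    chrom = sub.variants.chrom
    n_loci = sub.n_snps

    if not miss.any():
        S_pair_mean = float(values.shape[0])
        std = values.std(axis=0)
        poly = std > 0
        Z = (values - values.mean(axis=0)) / np.where(poly, std, 1.0)
        C = (Z.T @ Z) / values.shape[0]
        R2 = C**2
        iu, ju = np.triu_indices(n_loci, k=1)
        ok = (chrom[iu] != chrom[ju]) & poly[iu] & poly[ju]
        if not ok.any():
            raise ValueError("no inter-chromosomal pairs")
        r2_vals = R2[iu[ok], ju[ok]]
        weights = np.full(r2_vals.shape, values.shape[0], dtype=np.float64)
    else:
        r2_list, w_list = [], []
        for a in range(n_loci):
            for b in range(a + 1, n_loci):
                if chrom[a] == chrom[b]:
                    continue
                both = ~miss[:, a] & ~miss[:, b]
                nn = int(both.sum())
                if nn < 2:
                    continue
                x, y = values[both, a], values[both, b]
                if x.std() == 0 or y.std() == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                r2_list.append(r * r)
                w_list.append(nn)
        if not r2_list:
            raise ValueError("no inter-chromosomal pairs")
        r2_vals = np.array(r2_list)
        weights = np.array(w_list, dtype=np.float64)
        S_pair_mean = len(weights) / (1.0 / weights).sum()

    mean_r2 = float(np.average(r2_vals, weights=weights))
    S = float(S_pair_mean)
    if S < 30:
        raise ValueError("harmonic-mean sample size below 30; bias formula not applicable")
    expected = 1.0 / S + 3.19 / S**2

    def ne_from_drift(r2d: float) -> float:
        if r2d <= 0:
            return np.inf
        disc = 1.0 / 9.0 - 2.76 * r2d
        if disc < 0:
            disc = 0.0
        return (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2d)

    drift = mean_r2 - expected
    ne = ne_from_drift(drift)

    # parametric CI on mean r2 via chi-square with n_eff = number of loci
    n_eff = n_loci
    alpha = 1.0 - ci_level
    q_lo = stats.chi2.ppf(1 - alpha / 2, n_eff)
    q_hi = stats.chi2.ppf(alpha / 2, n_eff)
    r2_lo = mean_r2 * n_eff / q_lo
    r2_hi = mean_r2 * n_eff / q_hi
    ci_high = ne_from_drift(r2_lo - expected)
    ci_low = ne_from_drift(r2_hi - expected)

    return NeEstimate(
        ne=float(ne),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        S=S,
        n_pairs=int(len(r2_vals)),
        mean_r2=mean_r2,
        expected_sample_r2=float(expected),
        r2_drift=float(drift),
    )
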