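"""Haplotype-homozygosity statistics and the cross-population XP-EHH scan.

All statistics are unpolarized: the site-specific extended haplotype
homozygosity (EHHS) does not require ancestral/derived allele calls. For a
core SNP, haplotypes are grouped by identity over the site set extending
outward from the core; with group sizes n_h among n haplotypes the
unstandardized homozygosity is

    h(x) = sum_h n_h (n_h - 1) / (n (n - 1))

and EHHS(x) = h(x) / h(core). iES is the trapezoidal integral of EHHS over
physical distance in both directions, truncated where EHHS drops below the
cutoff (or a position gap exceeds ``max_gap_bp``). XP-EHH compares two
populations at each SNP as ln(iES_A / iES_B), standardized over the genome;
candidate regions are overlapping 100-kb windows (10-kb step) holding at
least three FDR-significant SNPs, merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .popstruct import bh_qvalues
from .variant_io import HaplotypeSet, VariantTable

logger = logging.getLogger(__name__)

__all__ = [
    "EhhsProfile",
    "XpehhTable",
    "CandidateRegion",
    "ehhs",
    "ies",
    "xpehh_scan",
    "candidate_regions",
]


@dataclass(frozen=True)
class EhhsProfile:
    core_index: int
    positions: np.ndarray  # bp, ascending; includes the core position
    ehhs: np.ndarray  # values in [0, 1], 1 at the core
    cutoff: float


@dataclass(frozen=True)
class XpehhTable:
    table: pd.DataFrame  # chrom,pos,locus_id,ies_a,ies_b,raw,std,p,q,favored
    alpha: float
    n_dropped: int


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int  # bp, closed interval
    end: int
    n_sig: int
    population_favored: str  # "A", "B" or "A|B" on ties


def _homozygosity(groups: np.ndarray, n: int) -> float:
    _, counts = np.unique(groups, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehhs(
    haps: HaplotypeSet,
    core: int,
    cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
) -> EhhsProfile:
    """Site-EHH profile around a core SNP, extended in both directions.

    Extension in a direction stops when EHHS falls below ``cutoff`` (the
    crossing point is kept in the profile) or when the gap to the next SNP
    exceeds ``max_gap_bp``. Only SNPs on the core's chromosome are used.
    """
    n = haps.n_haplotypes
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    V = haps.values
    pos = haps.variants.pos
    chrom = haps.variants.chrom
    core_chrom = chrom[core]

    groups0 = V[:, core].astype(np.int64)
    h_core = _homozygosity(groups0, n)
    if h_core == 0:
        # every haplotype unique already at the core (impossible for binary
        # alleles with n > 2, but guard the division)
        return EhhsProfile(core, np.array([pos[core]]), np.array([1.0]), cutoff)

    out_pos = [int(pos[core])]
    out_val = [1.0]

    for direction in (+1, -1):
        groups = groups0.copy()
        j = core
        prev_pos = pos[core]
        while True:
            j += direction
            if j < 0 or j >= haps.n_snps or chrom[j] != core_chrom:
                break
            if abs(int(pos[j]) - int(prev_pos)) > max_gap_bp:
                break
            groups = groups * 2 + V[:, j]
            # recompact to avoid overflow on long extensions
            _, groups = np.unique(groups, return_inverse=True)
            e = _homozygosity(groups, n) / h_core
            out_pos.append(int(pos[j]))
            out_val.append(e)
            prev_pos = pos[j]
            if e < cutoff:
                break

    order = np.argsort(out_pos)
    return EhhsProfile(core, np.array(out_pos)[order], np.array(out_val)[order], cutoff)


def ies(profile: EhhsProfile) -> float:
    """Trapezoidal integral of EHHS over bp across both directions."""
    if len(profile.positions) == 0:
        raise ValueError("empty profile")
    if len(profile.positions) == 1:
        return 0.0
    return float(np.trapezoid(profile.ehhs, profile.positions))


def _ies_all(haps: HaplotypeSet, cutoff: float, max_gap_bp: int) -> np.ndarray:
    out = np.empty(haps.n_snps)
    for j in range(haps.n_snps):
        out[j] = ies(ehhs(haps, j, cutoff, max_gap_bp))
    return out


def xpehh_scan(
    haps_a: HaplotypeSet,
    haps_b: HaplotypeSet,
    alpha: float = 0.05,
    cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
    min_finite: int = 50,
) -> XpehhTable:
    """Unpolarized XP-EHH between two phased cohorts sharing a variant table.

    raw = ln(iES_A / iES_B); std standardizes raw by its genome-wide mean and
    SD; p is the two-sided normal tail; q by Benjamini-Hochberg. SNPs where
    either iES is zero/undefined are dropped (count reported). Positive std
    favors population A (longer haplotype homozygosity in A).
    """
    if not np.array_equal(haps_a.variants.pos, haps_b.variants.pos) or not np.array_equal(
        haps_a.variants.chrom, haps_b.variants.chrom
    ):
        raise ValueError("both cohorts must share one variant table")
    ies_a = _ies_all(haps_a, cutoff, max_gap_bp)
    ies_b = _ies_all(haps_b, cutoff, max_gap_bp)
    with np.errstate(invalid="ignore", divide="ignore"):
        # difference of logs (not log of ratio) so that swapping the two
        # cohorts negates raw exactly, bit for bit
        raw = np.log(ies_a) - np.log(ies_b)
    finite = np.isfinite(raw)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("xpehh_scan: dropped %d SNPs with zero/undefined iES", n_dropped)
    if finite.sum() < min_finite:
        raise ValueError(
            f"only {int(finite.sum())} finite XP-EHH values; need >= {min_finite} "
            "to standardize"
        )
    mu = raw[finite].mean()
    sd = raw[finite].std(ddof=0)
    std = np.where(finite, (raw - mu) / sd, np.nan)
    p = np.where(finite, 2 * stats.norm.sf(np.abs(std)), np.nan)
    q = np.full_like(p, np.nan)
    q[finite] = bh_qvalues(p[finite])
    v = haps_a.variants
    table = pd.DataFrame(
        {
            "chrom": v.chrom,
            "pos": v.pos,
            "locus_id": v.locus_id,
            "ies_a": ies_a,
            "ies_b": ies_b,
            "raw": raw,
            "std": std,
            "p": p,
            "q": q,
            "population_favored": np.where(std > 0, "A", "B"),
        }
    )
    table.loc[~finite, "population_favored"] = ""
    return XpehhTable(table, alpha, n_dropped)


def candidate_regions(
    table: XpehhTable,
    variants: VariantTable | None = None,
    window_bp: int = 100_000,
    step_bp: int = 10_000,
    min_sig: int = 3,
    alpha: float | None = None,
) -> tuple[list[CandidateRegion], pd.DataFrame]:
    """Sliding-window candidate regions from FDR-significant scan SNPs.

    Each chromosome is tiled with windows of ``window_bp`` advancing by
    ``step_bp`` from position 1. A window qualifies when at least ``min_sig``
    SNPs with q < alpha fall inside; overlapping qualifying windows merge.
    The favored population per region follows the majority sign of its
    significant SNPs' std (ties report both). Returns the region list and
    the scan table with an ``in_region`` column (significant SNPs outside
    every region are thereby de-emphasized).
    """
    if alpha is None:
        alpha = table.alpha
    df = table.table
    sig = df[(df["q"] < alpha)].copy()
    regions: list[CandidateRegion] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        stdv = grp["std"].to_numpy()
        if len(pos) == 0:
            continue
        max_pos = int(df.loc[df["chrom"] == chrom, "pos"].max())
        starts = np.arange(1, max_pos + 1, step_bp)
        qual: list[tuple[int, int]] = []
        for s in starts:
            e = s + window_bp - 1
            inside = (pos >= s) & (pos <= e)
            if inside.sum() >= min_sig:
                qual.append((int(s), int(e)))
        # merge overlapping qualifying windows
        merged: list[list[int]] = []
        for s, e in qual:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            inside = (pos >= s) & (pos <= e)
            n_sig = int(inside.sum())
            pos_n = int((stdv[inside] > 0).sum())
            neg_n = int((stdv[inside] < 0).sum())
            if pos_n > neg_n:
                fav = "A"
            elif neg_n > pos_n:
                fav = "B"
            else:
                fav = "A|B"
            regions.append(CandidateRegion(str(chrom), s, e, n_sig, fav))

    in_region = np.zeros(len(df), dtype=bool)
    for r in regions:
        in_region |= (
            (df["chrom"] == r.chrom) & (df["pos"] >= r.start) & (df["pos"] <= r.end)
        ).to_numpy()
    annotated = df.copy()
    annotated["in_region"] = in_region
    return regions, annotated


def regions_to_bed(regions: list[CandidateRegion]) -> pd.DataFrame:
    """Candidate regions as a 0-based half-open BED frame."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start - 1 for r in regions],
            "end": [r.end for r in regions],
            "n_sig": [r.n_sig for r in regions],
            "favored": [r.population_favored for r in regions],
        }
    )
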