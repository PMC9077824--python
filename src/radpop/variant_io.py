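"""VCF and metadata I/O, SNP quality-control filters, and the shared data model.

The data model mirrors how RAD-capture SNP panels are analysed in practice:

* :class:`VariantTable` — genomic coordinates of biallelic SNPs (VCF 1-based).
* :class:`GenotypeMatrix` — individuals x SNPs alt-allele dosages with optional
  per-genotype allele depths (needed by the HDPlot paralog filter).
* :class:`HaplotypeSet` — phased 2N x SNPs binary matrix for haplotype
  homozygosity statistics, which require complete phased data.
* :class:`PopulationMap` — individual -> site / population labels, with
  optional ancestry proportions (a Q matrix) used for population assignment.

Filters implemented: per-SNP (optionally per-population) missingness, minor
allele frequency, HDPlot paralog flagging from heterozygote read-ratio
deviation, and greedy sliding-window LD pruning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype in dosage matrices.
MISSING: int = -1

#: Label for individuals that cannot be assigned to a population.
UNASSIGNED: str = "UNASSIGNED"


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantTable:
    """Coordinates and alleles of biallelic SNPs.

    Positions are 1-based base pairs, as in VCF. Within each chromosome
    positions must be strictly increasing and every ``locus_id`` is unique.
    """

    chrom: np.ndarray  # object / str array, length n_snps
    pos: np.ndarray  # int64, 1-based
    ref: np.ndarray  # single-character alleles
    alt: np.ndarray
    locus_id: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name in ("chrom", "ref", "alt", "locus_id"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"VariantTable field {name!r} length mismatch")
        if len(np.unique(self.locus_id)) != n:
            raise ValueError("locus_id values must be unique")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def take(self, idx: np.ndarray) -> "VariantTable":
        return VariantTable(
            self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx], self.locus_id[idx]
        )

    def region_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of SNPs inside the closed interval [start, end] on chrom."""
        return (self.chrom == chrom) & (self.pos >= start) & (self.pos <= end)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
                "locus_id": self.locus_id,
            }
        )

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "VariantTable":
        return VariantTable(
            df["chrom"].to_numpy(dtype=object),
            df["pos"].to_numpy(dtype=np.int64),
            df["ref"].to_numpy(dtype=object),
            df["alt"].to_numpy(dtype=object),
            df["locus_id"].to_numpy(dtype=object),
        )


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix with optional allele depths.

    ``values[i, j]`` is the count of alternate alleles {0, 1, 2} carried by
    individual ``i`` at SNP ``j``, or :data:`MISSING`. ``depths``, when
    present, is an ``n_individuals x n_snps x 2`` array of
    ``(ref_reads, alt_reads)``.
    """

    values: np.ndarray  # int8, n_ind x n_snps
    variants: VariantTable
    samples: list[str]
    depths: np.ndarray | None = None  # int32, n_ind x n_snps x 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"genotype shape {self.values.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.depths is not None and self.depths.shape[:2] != self.values.shape:
            raise ValueError("depths shape inconsistent with genotypes")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing genotypes (NaN if none)."""
        vals = self.values.astype(np.float64)
        vals[self.values == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(vals, axis=0) / 2.0

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values[:, idx],
            self.variants.take(idx),
            list(self.samples),
            None if self.depths is None else self.depths[:, idx],
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[idx],
            self.variants,
            [self.samples[i] for i in np.atleast_1d(idx)],
            None if self.depths is None else self.depths[idx],
        )


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes; rows ``2i`` and ``2i+1`` belong to individual ``i``."""

    values: np.ndarray  # uint8, 2*n_ind x n_snps, no missing entries
    variants: VariantTable
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype row count must be 2 x n_individuals")
        if self.values.shape[1] != len(self.variants):
            raise ValueError("haplotype column count must equal variant count")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("haplotypes must be binary with no missing entries")

    @property
    def n_haplotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def take_snps(self, idx: np.ndarray) -> "HaplotypeSet":
        return HaplotypeSet(self.values[:, idx], self.variants.take(idx), list(self.samples))

    def take_individuals(self, idx: Sequence[int]) -> "HaplotypeSet":
        rows = np.ravel([(2 * i, 2 * i + 1) for i in idx])
        return HaplotypeSet(self.values[rows], self.variants, [self.samples[i] for i in idx])

    def to_genotypes(self) -> GenotypeMatrix:
        dos = (self.values[0::2] + self.values[1::2]).astype(np.int8)
        return GenotypeMatrix(dos, self.variants, list(self.samples))


@dataclass
class PopulationMap:
    """Individual -> site and population labels, with optional Q matrix.

    ``q`` rows (ancestry proportions over K clusters) must sum to 1 within
    1e-6. Individuals without a confident population are labelled
    :data:`UNASSIGNED`.
    """

    site: dict[str, str]
    population: dict[str, str] = field(default_factory=dict)
    q: pd.DataFrame | None = None  # index: individual id, columns: cluster labels

    def __post_init__(self) -> None:
        for ind in self.site:
            self.population.setdefault(ind, UNASSIGNED)
        if self.q is not None:
            sums = self.q.sum(axis=1).to_numpy()
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValueError("Q rows must sum to 1 within 1e-6")

    def populations(self) -> list[str]:
        pops = sorted({p for p in self.population.values() if p != UNASSIGNED})
        return pops

    def members(self, pop: str, samples: Sequence[str]) -> np.ndarray:
        """Indices (into ``samples``) of individuals assigned to ``pop``."""
        return np.array(
            [i for i, s in enumerate(samples) if self.population.get(s) == pop], dtype=np.intp
        )

    def labels_for(self, samples: Sequence[str]) -> np.ndarray:
        return np.array([self.population.get(s, UNASSIGNED) for s in samples], dtype=object)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_vcf(path: str, require_phased: bool = False):
    """Read a VCF of biallelic SNPs.

    Non-biallelic or non-SNP records are skipped (count logged). Dosages come
    from GT; AD fields, when present, populate depths. A
    :class:`HaplotypeSet` is returned only when every GT is phased and
    complete, otherwise ``None``.

    Parameters
    ----------
    path:
        VCF file (plain or bgzipped).
    require_phased:
        If set, any unphased or missing genotype is a fatal error naming the
        offending SNP and individual.

    Returns
    -------
    (VariantTable, GenotypeMatrix, HaplotypeSet | None)
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    n = len(samples)

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    ids: list[str] = []
    dosage_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    any_depth = False
    all_phased = True
    skipped = 0

    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        gts = np.array(v.genotypes, dtype=object)  # n x [a0, a1, phased]
        a0 = np.array([g[0] for g in gts], dtype=np.int64)
        a1 = np.array([g[1] for g in gts], dtype=np.int64)
        phased = np.array([bool(g[2]) for g in gts])
        missing = (a0 < 0) | (a1 < 0)
        if require_phased and (missing.any() or not phased.all()):
            bad = int(np.flatnonzero(missing | ~phased)[0])
            raise ValueError(
                f"phased complete genotypes required but {v.CHROM}:{v.POS} "
                f"sample {samples[bad]!r} is "
                + ("missing" if missing[bad] else "unphased")
            )
        dos = (a0 + a1).astype(np.int8)
        dos[missing] = MISSING
        dosage_rows.append(dos)
        if missing.any() or not phased.all():
            all_phased = False
        hap_rows.append(np.stack([a0, a1], axis=1).reshape(-1))

        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is not None and ad.shape[1] >= 2:
            any_depth = True
            d = ad[:, :2].astype(np.int32)
            d[d < 0] = 0
            depth_rows.append(d)
        else:
            depth_rows.append(np.zeros((n, 2), dtype=np.int32))

        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")

    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)

    variants = VariantTable(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        np.array(ids, dtype=object),
    )
    values = (
        np.stack(dosage_rows, axis=1) if dosage_rows else np.zeros((n, 0), dtype=np.int8)
    )
    depths = np.stack(depth_rows, axis=1) if any_depth else None
    gm = GenotypeMatrix(values, variants, samples, depths)

    haps = None
    if all_phased and len(variants) > 0:
        hv = np.stack(hap_rows, axis=1).astype(np.uint8)
        haps = HaplotypeSet(hv, variants, samples)
    return variants, gm, haps


def write_vcf(path: str, gm: GenotypeMatrix, haps: HaplotypeSet | None = None) -> None:
    """Write a VCF v4.2 with GT (phased when ``haps`` given) and AD when present."""
    v = gm.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(v.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.depths is not None:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths for the ref and alt alleles">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        fmt = "GT:AD" if gm.depths is not None else "GT"
        for j in range(gm.n_snps):
            fields = [
                str(v.chrom[j]),
                str(v.pos[j]),
                str(v.locus_id[j]),
                str(v.ref[j]),
                str(v.alt[j]),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            for i in range(gm.n_individuals):
                d = gm.values[i, j]
                if haps is not None:
                    gt = f"{haps.values[2 * i, j]}|{haps.values[2 * i + 1, j]}"
                elif d == MISSING:
                    gt = "./."
                else:
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]
                if gm.depths is not None:
                    gt += f":{gm.depths[i, j, 0]},{gm.depths[i, j, 1]}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def read_metadata(path: str) -> PopulationMap:
    """Read a metadata TSV with columns id, site, pop and optional q1..qK."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    site = dict(zip(df["id"], df["site"].astype(str)))
    pop = (
        dict(zip(df["id"], df["pop"].astype(str))) if "pop" in df.columns else {}
    )
    qcols = [c for c in df.columns if c.startswith("q") and c[1:].isdigit()]
    q = df.set_index("id")[qcols] if qcols else None
    return PopulationMap(site, pop, q)


def write_metadata(path: str, pm: PopulationMap) -> None:
    ids = list(pm.site)
    out = pd.DataFrame(
        {
            "id": ids,
            "site": [pm.site[i] for i in ids],
            "pop": [pm.population.get(i, UNASSIGNED) for i in ids],
        }
    )
    if pm.q is not None:
        for k, col in enumerate(pm.q.columns, start=1):
            out[f"q{k}"] = pm.q[col].reindex(ids).to_numpy()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_missingness(
    gm: GenotypeMatrix,
    max_missing: float = 0.10,
    per_population: PopulationMap | None = None,
) -> GenotypeMatrix:
    """Retain SNPs whose missing-call fraction is <= ``max_missing``.

    With ``per_population`` the fraction is computed within every assigned
    population and the SNP must pass in all of them. SNP order is preserved.
    """
    if not 0 <= max_missing < 1:
        raise ValueError("max_missing must be in [0, 1)")
    miss = gm.missing_mask()
    if per_population is None:
        frac = miss.mean(axis=0)
        keep = frac <= max_missing
    else:
        keep = np.ones(gm.n_snps, dtype=bool)
        for pop in per_population.populations():
            idx = per_population.members(pop, gm.samples)
            if len(idx) == 0:
                continue
            keep &= miss[idx].mean(axis=0) <= max_missing
    if not keep.any():
        warnings.warn("filter_missingness removed every SNP", stacklevel=2)
    return gm.take_snps(np.flatnonzero(keep))


def filter_maf(gm: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Retain SNPs with minor-allele frequency >= ``min_maf`` (non-missing calls)."""
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    p = gm.allele_freq()
    maf = np.fmin(p, 1.0 - p)
    keep = maf >= min_maf
    keep &= ~np.isnan(p)
    if not keep.any():
        warnings.warn("filter_maf removed every SNP", stacklevel=2)
    return gm.take_snps(np.flatnonzero(keep))


def hdplot_flags(
    gm: GenotypeMatrix, max_H: float = 0.6, max_absD: float = 5.0
) -> pd.DataFrame:
    """HDPlot paralog statistics per SNP.

    ``H`` is the heterozygote proportion among non-missing genotypes. ``D`` is
    the z-score of the total ref-read count against a 1:1 binomial over reads
    of heterozygous individuals: ``D = (x - N/2) / sqrt(N/4)`` with ``x`` the
    summed ref reads and ``N`` the summed total reads. Collapsed paralogs show
    excess heterozygosity (high H) and skewed read ratios (large |D|).

    Returns a frame with columns ``locus_id, H, D, keep``; ``keep`` is true
    iff ``H <= max_H`` and ``|D| <= max_absD``. SNPs with zero heterozygotes
    get ``H = 0, D = 0``.
    """
    if gm.depths is None:
        raise ValueError("hdplot_flags requires allele depths")
    het = gm.values == 1
    nonmiss = gm.values != MISSING
    n_nm = nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(n_nm > 0, het.sum(axis=0) / np.maximum(n_nm, 1), 0.0)

    tot = gm.depths.sum(axis=2)  # n_ind x n_snps total reads
    no_depth_het = het & (tot == 0)
    if no_depth_het.any():
        warnings.warn(
            f"{int(no_depth_het.sum())} heterozygous genotypes lack read depths; "
            "excluded from D",
            stacklevel=2,
        )
    use = het & (tot > 0)
    x = np.where(use, gm.depths[:, :, 0], 0).sum(axis=0).astype(np.float64)
    N = np.where(use, tot, 0).sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(N > 0, (x - N / 2.0) / np.sqrt(N / 4.0), 0.0)
    H = np.where(het.sum(axis=0) == 0, 0.0, H)
    keep = (H <= max_H) & (np.abs(D) <= max_absD)
    return pd.DataFrame(
        {"locus_id": gm.variants.locus_id, "H": H, "D": D, "keep": keep}
    )


def _dosage_r2(values: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage columns over shared non-missing calls."""
    a, b = values[:, i], values[:, j]
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(np.float64)
    y = b[ok].astype(np.float64)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def prune_ld(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.5,
) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning of dosage r².

    Within each window (per chromosome), while any retained pair exceeds the
    r² threshold the member with the lower MAF is removed (ties break toward
    the later position). Deterministic for fixed input.
    """
    if not window_snps >= step_snps >= 1:
        raise ValueError("require window_snps >= step_snps >= 1")
    p = gm.allele_freq()
    maf = np.fmin(p, 1.0 - p)
    keep = np.ones(gm.n_snps, dtype=bool)
    for c in pd.unique(gm.variants.chrom):
        cidx = np.flatnonzero(gm.variants.chrom == c)
        start = 0
        while start < len(cidx):
            win = cidx[start : start + window_snps]
            _prune_window(gm.values, maf, win, keep, r2_threshold)
            if start + window_snps >= len(cidx):
                break
            start += step_snps
    return gm.take_snps(np.flatnonzero(keep))


def _prune_window(
    values: np.ndarray,
    maf: np.ndarray,
    win: np.ndarray,
    keep: np.ndarray,
    thr: float,
) -> None:
    while True:
        active = win[keep[win]]
        worst = None  # (r2, i, j)
        for a in range(len(active)):
            for b in range(a + 1, len(active)):
                r2 = _dosage_r2(values, active[a], active[b])
                if r2 > thr and (worst is None or r2 > worst[0]):
                    worst = (r2, active[a], active[b])
        if worst is None:
            return
        _, i, j = worst
        # drop the lower-MAF member; tie -> later position
        if maf[i] == maf[j]:
            drop = max(i, j)
        elif maf[i] < maf[j]:
            drop = i
        else:
            drop = j
        keep[drop] = False


def assign_populations(pm: PopulationMap, threshold: float = 0.85) -> PopulationMap:
    """Assign each individual to the cluster where its Q exceeds ``threshold``.

    Strict inequality: an individual with max Q exactly at the threshold stays
    :data:`UNASSIGNED`. Individuals lacking a Q row are UNASSIGNED with a
    warning.
    """
    if pm.q is None:
        raise ValueError("assign_populations requires a Q matrix")
    pop: dict[str, str] = {}
    n_missing = 0
    for ind in pm.site:
        if ind not in pm.q.index:
            pop[ind] = UNASSIGNED
            n_missing += 1
            continue
        row = pm.q.loc[ind]
        k = row.idxmax()
        pop[ind] = str(k) if row[k] > threshold else UNASSIGNED
    if n_missing:
        warnings.warn(f"{n_missing} individuals lack Q rows; left UNASSIGNED", stacklevel=2)
    return PopulationMap(dict(pm.site), pop, pm.q)


def filter_report(gm_before: GenotypeMatrix, hd: pd.DataFrame, path: str) -> None:
    """Write a TSV of HDPlot statistics and drop reasons."""
    out = hd.copy()
    out["reason_dropped"] = np.where(out["keep"], "", "hdplot")
    out.rename(columns={"locus_id": "snp"}).to_csv(path, sep="\t", index=False)
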