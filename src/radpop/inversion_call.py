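"""Four-step putative chromosomal-inversion test.

A segregating inversion suppresses recombination between arrangements, so a
region harbouring one shows (1) elevated linkage disequilibrium, (2) three
discrete clusters of individuals along PC1 of a region-restricted PCA (the
two homokaryotypes and the heterokaryotype), (3) elevated heterozygosity in
the middle cluster, and (4) arrangement frequencies that differ between
populations. This module implements each step: regional LD summaries against
the chromosomal background, regional PCA with k-means (k=3) karyotyping and
a cluster-discreteness statistic (between-cluster sum of squares over total),
Wilcoxon rank-sum contrasts of per-individual heterozygosity among clusters,
and per-site/per-population karyotype frequency tables with a heuristic
"assumed derived" arrangement call (the homokaryotype with lower
heterozygosity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import LdPairList
from .popstruct import _standardize
from .variant_io import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "GenomicRegion",
    "KaryotypeCall",
    "regional_ld_summary",
    "regional_pca_karyotype",
    "het_by_cluster",
    "karyotype_frequencies",
]

#: Karyotype labels for the three PC1 clusters, ordered by PC1 centroid.
HOM_A, HET, HOM_B = "HOM_A", "HET", "HOM_B"


@dataclass(frozen=True)
class GenomicRegion:
    """Closed 1-based interval [start, end] on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("region start must be < end")

    @staticmethod
    def parse(spec: str) -> "GenomicRegion":
        """Parse ``chrom:start-end`` (commas in numbers allowed)."""
        chrom, rng = spec.rsplit(":", 1)
        s, e = (int(x.replace(",", "")) for x in rng.split("-"))
        return GenomicRegion(chrom, s, e)


@dataclass
class KaryotypeCall:
    samples: list[str]
    cluster: np.ndarray  # 1, 2, 3 ordered along PC1 (0 = uncalled)
    karyotype: np.ndarray  # HOM_A / HET / HOM_B labels
    het: np.ndarray  # per-individual heterozygous fraction over region SNPs
    pc1: np.ndarray
    n_clusters_found: int
    flagged_degenerate: bool = False


def regional_ld_summary(
    pairs: LdPairList,
    region: GenomicRegion,
    variants,
) -> dict:
    """Mean/max r² inside the region vs the same-chromosome background.

    ``pairs`` must have been computed over the region's chromosome;
    background pairs have at least one SNP outside the region. The reporting
    floor used when computing the pairs is echoed in the summary.
    """
    df = pairs.pairs
    inside = variants.region_mask(region.chrom, region.start, region.end)
    n_in = int(inside.sum())
    if n_in < 3:
        raise ValueError(f"only {n_in} SNPs inside the region; need >= 3")
    on_chrom = variants.chrom == region.chrom
    i_in = inside[df["snp_i"].to_numpy()]
    j_in = inside[df["snp_j"].to_numpy()]
    both_chrom = on_chrom[df["snp_i"].to_numpy()] & on_chrom[df["snp_j"].to_numpy()]
    reg = df[i_in & j_in]
    bg = df[both_chrom & ~(i_in & j_in)]
    return {
        "mean_r2": float(reg["r2"].mean()) if len(reg) else np.nan,
        "max_r2": float(reg["r2"].max()) if len(reg) else np.nan,
        "background_mean_r2": float(bg["r2"].mean()) if len(bg) else np.nan,
        "n_region_pairs": int(len(reg)),
        "n_background_pairs": int(len(bg)),
        "report_floor": pairs.report_floor,
    }


def _kmeans_1d(x: np.ndarray, k: int, seed: int, n_restarts: int = 100):
    """Seeded k-means on a 1-D array with restarts; returns labels and inertia.

    Uses scikit-learn's Lloyd iterations; the best of ``n_restarts`` random
    initialisations (minimal within-cluster sum of squares) is kept, making
    the partition reproducible for a fixed seed.
    """
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(x.reshape(-1, 1))
    return labels, km.inertia_, km.cluster_centers_.ravel()


def regional_pca_karyotype(
    gm: GenotypeMatrix,
    region: GenomicRegion,
    seed: int = 0,
    use_pc2: bool = False,
) -> tuple[KaryotypeCall, float]:
    """Regional PCA + k-means (k=3) karyotyping with a discreteness statistic.

    PCA is restricted to region SNPs (standardized as in the genome-wide
    PCA); k-means with k=3 runs on PC1 scores (optionally PC1-2) with 100
    seeded restarts; clusters are ordered by PC1 centroid and labelled
    HOM_A / HET / HOM_B, the middle cluster being the putative
    heterokaryotype. Discreteness is the between-cluster sum of squares over
    the total sum of squares of the clustered scores.
    """
    idx = np.flatnonzero(gm.variants.region_mask(region.chrom, region.start, region.end))
    if len(idx) < 3:
        raise ValueError("need >= 3 SNPs in the region")
    sub = gm.take_snps(idx)
    if sub.n_individuals < 6:
        raise ValueError("need >= 6 individuals")
    Z, _ = _standardize(sub)
    Zc = Z - Z.mean(axis=0)
    U, s, _ = np.linalg.svd(Zc, full_matrices=False)
    ncomp = 2 if use_pc2 else 1
    scores = U[:, :ncomp] * s[:ncomp]
    pc1 = scores[:, 0]

    labels, inertia, centers = _kmeans_1d(
        scores[:, 0] if not use_pc2 else scores, k=3, seed=seed
    )
    found = len(np.unique(labels))
    flagged = found < 3
    if flagged:
        warnings.warn(
            f"k-means found only {found} non-empty clusters in the region",
            stacklevel=2,
        )

    # order clusters along PC1
    order = np.argsort([pc1[labels == c].mean() for c in range(3)])
    rank = np.empty(3, dtype=int)
    rank[order] = np.arange(1, 4)
    cluster = rank[labels]
    karyo_map = {1: HOM_A, 2: HET, 3: HOM_B}
    karyotype = np.array([karyo_map[c] for c in cluster], dtype=object)

    total_ss = float(((pc1 - pc1.mean()) ** 2).sum()) if not use_pc2 else float(
        ((scores - scores.mean(axis=0)) ** 2).sum()
    )
    within = 0.0
    basis = pc1.reshape(-1, 1) if not use_pc2 else scores
    for c in (1, 2, 3):
        m = cluster == c
        if m.any():
            within += float(((basis[m] - basis[m].mean(axis=0)) ** 2).sum())
    discreteness = (total_ss - within) / total_ss if total_ss > 0 else 0.0

    het = _region_het(sub)
    call = KaryotypeCall(
        samples=list(gm.samples),
        cluster=cluster,
        karyotype=karyotype,
        het=het,
        pc1=pc1,
        n_clusters_found=found,
        flagged_degenerate=flagged,
    )
    return call, float(discreteness)


def _region_het(sub: GenotypeMatrix) -> np.ndarray:
    nm = sub.values != MISSING
    het = sub.values == 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nm.sum(axis=1) > 0, het.sum(axis=1) / nm.sum(axis=1), np.nan)


def het_by_cluster(call: KaryotypeCall, alpha: float = 0.05) -> dict:
    """Pairwise Wilcoxon rank-sum tests of per-individual heterozygosity.

    Three two-sided tests (normal approximation with tie correction) between
    the clusters; the confirmation flag is set iff the middle (HET) cluster's
    median heterozygosity exceeds both homokaryote clusters with p < alpha in
    both comparisons. Clusters with < 3 members flag the result low-power.
    """
    groups = {}
    for lab in (HOM_A, HET, HOM_B):
        h = call.het[call.karyotype == lab]
        groups[lab] = h[np.isfinite(h)]
        if len(groups[lab]) == 0:
            raise ValueError(f"cluster {lab} is empty")
    low_power = any(len(g) < 3 for g in groups.values())
    tests = {}
    for a, b in ((HOM_A, HET), (HET, HOM_B), (HOM_A, HOM_B)):
        res = stats.mannwhitneyu(
            groups[a], groups[b], alternative="two-sided", method="asymptotic"
        )
        tests[f"{a}_vs_{b}"] = float(res.pvalue)
    med = {lab: float(np.median(g)) for lab, g in groups.items()}
    confirmed = (
        med[HET] > med[HOM_A]
        and med[HET] > med[HOM_B]
        and tests[f"{HOM_A}_vs_{HET}"] < alpha
        and tests[f"{HET}_vs_{HOM_B}"] < alpha
    )
    return {
        "pvalues": tests,
        "medians": med,
        "confirmed": bool(confirmed),
        "low_power": bool(low_power),
        "alpha": alpha,
    }


def karyotype_frequencies(
    call: KaryotypeCall, pm: PopulationMap
) -> dict:
    """Karyotype proportions per site and per population, plus a derived call.

    Rows sum to 1. Unassigned individuals form their own population row. The
    "assumed derived" arrangement is the homokaryote cluster whose members
    have lower mean regional heterozygosity; an exact tie is reported as a
    tie rather than silently broken.
    """
    def _freq_table(labels: np.ndarray) -> pd.DataFrame:
        rows = {}
        for lab in pd.unique(labels):
            m = labels == lab
            tot = int(m.sum())
            rows[lab] = [
                float((call.karyotype[m] == k).sum() / tot) for k in (HOM_A, HET, HOM_B)
            ]
        return pd.DataFrame.from_dict(rows, orient="index", columns=[HOM_A, HET, HOM_B])

    site_labels = np.array([pm.site.get(s, "UNKNOWN") for s in call.samples], dtype=object)
    pop_labels = pm.labels_for(call.samples)

    mean_het = {}
    for lab in (HOM_A, HOM_B):
        h = call.het[call.karyotype == lab]
        mean_het[lab] = float(np.nanmean(h)) if len(h) else np.nan
    if np.isclose(mean_het[HOM_A], mean_het[HOM_B]):
        derived = "TIE"
    elif mean_het[HOM_A] < mean_het[HOM_B]:
        derived = HOM_A
    else:
        derived = HOM_B

    return {
        "by_site": _freq_table(site_labels),
        "by_population": _freq_table(pop_labels),
        "assumed_derived": derived,
        "hom_mean_het": mean_het,
    }
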