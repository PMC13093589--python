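"""SNP filtering, KING-robust kinship, and Weir-Cockerham FST.

Kinship uses the between-family KING-robust estimator computed from
identity-state counts,

    phi_ij = (N_het,het - 2 * N_oppHom) / (N_het_i + N_het_j),

with all counts restricted to loci called in both individuals.  The
denominator is the *sum* of the two individuals' heterozygote counts
(the convention of vcftools --relatedness2), under which a self-pair is
exactly 0.5, full sibs are near 0.25, and half sibs near 0.125.

FST between two groups is the Weir-Cockerham theta per locus (two
populations, genotype-based, with the heterozygosity correction),
averaged over loci with a defined denominator; negative per-locus values
are retained before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import GenotypeMatrix, MISSING, ValidationError, get_logger

__all__ = [
    "filter_genotypes",
    "FilterReport",
    "king_kinship",
    "KinshipMatrix",
    "mean_fst",
]


@dataclass
class FilterReport:
    """What each filtering stage removed, and what survived."""

    n_loci_in: int
    n_samples_in: int
    loci_removed_missing: list[str] = field(default_factory=list)
    individuals_removed: list[tuple[str, float]] = field(default_factory=list)
    loci_removed_maf: list[str] = field(default_factory=list)
    loci_retained: int = 0
    samples_retained: int = 0

    def __post_init__(self) -> None:
        pass

    def check_conservation(self) -> None:
        if (
            len(self.loci_removed_missing) + len(self.loci_removed_maf)
            + self.loci_retained != self.n_loci_in
            or len(self.individuals_removed) + self.samples_retained
            != self.n_samples_in
        ):
            raise ValidationError("filter report does not conserve totals")


def filter_genotypes(
    geno: GenotypeMatrix,
    locus_missing_max: float = 0.20,
    indiv_missing_max: float = 0.20,
    maf_min: float = 0.01,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the three-stage SNP filter in its fixed order.

    1. remove loci missing in more than ``locus_missing_max`` of
       individuals;
    2. remove individuals with more than ``indiv_missing_max`` missing
       calls (over the surviving loci);
    3. remove invariant loci and loci with minor allele frequency below
       ``maf_min`` (allele frequencies computed after individual
       removal).
    """
    g = geno.genotypes
    n_samples, n_loci = g.shape
    report = FilterReport(n_loci_in=n_loci, n_samples_in=n_samples)

    miss = g == MISSING
    locus_missing = miss.mean(axis=0)
    keep_loci = locus_missing <= locus_missing_max
    report.loci_removed_missing = [
        geno.locus_ids[j] for j in np.flatnonzero(~keep_loci)
    ]
    g = g[:, keep_loci]
    loci = [geno.locus_ids[j] for j in np.flatnonzero(keep_loci)]

    if g.shape[1] == 0:
        raise ValidationError("all loci removed by the missingness filter")
    indiv_missing = (g == MISSING).mean(axis=1)
    keep_ind = indiv_missing <= indiv_missing_max
    report.individuals_removed = [
        (geno.sample_ids[i], float(indiv_missing[i]))
        for i in np.flatnonzero(~keep_ind)
    ]
    g = g[keep_ind, :]
    samples = [geno.sample_ids[i] for i in np.flatnonzero(keep_ind)]

    called = g != MISSING
    with np.errstate(invalid="ignore"):
        p = np.where(
            called.sum(axis=0) > 0,
            np.where(g == MISSING, 0, g).sum(axis=0) / (2.0 * called.sum(axis=0)),
            np.nan,
        )
    maf = np.minimum(p, 1.0 - p)
    keep_maf = np.isfinite(maf) & (maf >= maf_min) & (p > 0) & (p < 1)
    report.loci_removed_maf = [loci[j] for j in np.flatnonzero(~keep_maf)]
    g = g[:, keep_maf]
    loci = [loci[j] for j in np.flatnonzero(keep_maf)]

    if not loci:
        raise ValidationError("all loci removed by filtering")
    report.loci_retained = len(loci)
    report.samples_retained = len(samples)
    report.check_conservation()
    return GenotypeMatrix(samples, loci, g), report


@dataclass
class KinshipMatrix:
    """Symmetric pairwise kinship estimates; self-pairs are 0.5 by the
    estimator's identity.  Pairs with no shared informative loci are NaN."""

    sample_ids: list[str]
    phi: np.ndarray

    def pair(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.phi[i, j])


def king_kinship(geno: GenotypeMatrix) -> KinshipMatrix:
    """KING-robust pairwise kinship from 0/1/2 genotypes."""
    log = get_logger("recipcross.popgen")
    g = geno.genotypes
    het = (g == 1).astype(np.float64)
    hom0 = (g == 0).astype(np.float64)
    hom2 = (g == 2).astype(np.float64)
    valid = (g != MISSING).astype(np.float64)

    n_hethet = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    # heterozygote count of i over loci also called in j
    het_i = het @ valid.T
    denom = het_i + het_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    n_undef = int(np.isnan(phi).sum())
    if n_undef:
        log.warning("%d sample pair(s) with zero shared heterozygous loci", n_undef)
    return KinshipMatrix(list(geno.sample_ids), phi)


def _wc_theta_components(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components a and b+c per locus for r=2
    populations, vectorized over loci.  Returns (a, a+b+c)."""
    r = len(groups)
    n_i = np.stack([(sub != MISSING).sum(axis=0) for sub in groups]).astype(float)
    alt = np.stack(
        [np.where(sub == MISSING, 0, sub).sum(axis=0) for sub in groups]
    ).astype(float)
    hets = np.stack([(sub == 1).sum(axis=0) for sub in groups]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_i = alt / (2.0 * n_i)
        h_i = hets / n_i
    nbar = n_i.mean(axis=0)
    sum_n = n_i.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (sum_n - (n_i**2).sum(axis=0) / sum_n) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / sum_n
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / sum_n
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    defined = (n_i >= 1).all(axis=0) & (nbar > 1) & np.isfinite(nc) & (nc > 0)
    a = np.where(defined, a, np.nan)
    total = np.where(defined, a + b + c, np.nan)
    return a, total


def mean_fst(
    geno: GenotypeMatrix, group_a: list[str], group_b: list[str]
) -> tuple[np.ndarray, float]:
    """Per-locus Weir-Cockerham theta between two sample groups + mean.

    The mean is over loci with a defined, nonzero denominator; negative
    per-locus values are retained.
    """
    if set(group_a) & set(group_b):
        raise ValidationError("FST groups must not overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each FST group needs at least 2 individuals")
    idx = {s: i for i, s in enumerate(geno.sample_ids)}
    missing_ids = [s for s in (*group_a, *group_b) if s not in idx]
    if missing_ids:
        raise ValidationError(f"unknown sample ids: {missing_ids[:5]}")
    sub_a = geno.genotypes[[idx[s] for s in group_a], :]
    sub_b = geno.genotypes[[idx[s] for s in group_b], :]
    a, total = _wc_theta_components([sub_a, sub_b])
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = a / total
    theta = np.where(np.isfinite(theta), theta, np.nan)
    defined = ~np.isnan(theta)
    if not defined.any():
        raise ValidationError("no locus with a defined FST denominator")
    return theta, float(np.nanmean(theta))
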