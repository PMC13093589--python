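"""Synthetic reciprocal-cross designs, RNA-seq counts, and genotypes.

Emulates the structure of the study system: M independent 2x2 crossing
matrices, each mating one hatchery-origin (H) and one natural-origin (N)
female to one H and one N male, giving the four cross types HH, HN, NH,
NN (mother first).  Two offspring (one female, one male) are sampled per
full-sib family, so a complete design has 8*M offspring.

Counts follow a negative-binomial model whose log2 mean is additive in
ancestry dose, parental-environment (maternal/paternal) indicators, sex,
cross-date batch, and a per-gene-per-family random intercept; a truth
table records every planted effect so downstream estimators can be
checked for parameter recovery.  Genotypes are produced by explicit
Mendelian transmission from simulated parents, so full sibs share both
parents and offspring of different cells of one matrix share exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CountMatrix, GenotypeMatrix, ValidationError, validate_metadata

__all__ = [
    "SimulationConfig",
    "simulate_design",
    "simulate_counts",
    "simulate_genotypes",
    "CROSS_DATES",
]

#: spawning dates used for the cross-date batches; matrices are assigned in
#: near-equal blocks (4/4/4/3 when M=15)
CROSS_DATES = ("2008-03-17", "2008-03-24", "2008-04-03", "2008-04-08")

# family-code letter per cross type (matrix number + letter, e.g. "3A")
_CELL_LETTERS = {"HH": "A", "NH": "B", "NN": "C", "HN": "D"}
_CROSS_ORDER = ("HH", "NH", "NN", "HN")  # A..D order within a matrix


@dataclass
class SimulationConfig:
    """Parameters of the count/genotype generating process.

    Effects are on the log2 scale.  ``up_fraction`` is the fraction of
    ancestry-affected genes upregulated in HH offspring (0.75 mirrors the
    observed direction bias).  ``family_effect_sd`` is calibrated so the
    sibling-correlation estimator recovers roughly 0.13 on default data.
    Gene classes are assigned to disjoint blocks of the gene list in the
    order ancestry, maternal, paternal, sex; the rest are null genes.
    """

    n_matrices: int = 15
    n_genes: int = 2000
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    dispersion: float = 0.1  # NB alpha: var = mu + alpha*mu^2
    dispersion_shape: float | None = None  # gamma shape; None = fixed alpha
    n_ancestry_genes: int = 300
    ancestry_effect: float = 2.0
    ancestry_effect_sd: float = 0.5
    up_fraction: float = 0.75
    n_maternal_genes: int = 20
    maternal_effect: float = 2.0
    n_paternal_genes: int = 20
    paternal_effect: float = 2.0
    n_sex_genes: int = 4
    sex_effect: float = 2.0
    batch_effect_sd: float = 0.1
    family_effect_sd: float = 0.26
    library_size_log2_sd: float = 0.25
    pool_freq_shift: float = 0.02  # H-vs-N parent allele-frequency shift
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_matrices < 1:
            raise ValidationError("n_matrices must be >= 1")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise ValidationError("up_fraction must lie in [0, 1]")
        if self.family_effect_sd < 0:
            raise ValidationError("family_effect_sd must be >= 0")
        n_effect = (
            self.n_ancestry_genes
            + self.n_maternal_genes
            + self.n_paternal_genes
            + self.n_sex_genes
        )
        if n_effect > self.n_genes:
            raise ValidationError(
                f"effect gene classes ({n_effect}) exceed n_genes ({self.n_genes})"
            )

    @classmethod
    def null(cls, n_genes: int = 2000, **kwargs) -> "SimulationConfig":
        """A no-effect configuration: every gene is a null gene and there
        is no family, batch, or planted biological signal."""
        return cls(
            n_genes=n_genes,
            n_ancestry_genes=0,
            n_maternal_genes=0,
            n_paternal_genes=0,
            n_sex_genes=0,
            batch_effect_sd=0.0,
            family_effect_sd=0.0,
            **kwargs,
        )


def _date_blocks(m: int) -> list[str]:
    """Assign M matrices to spawning dates in near-equal leading-heavy
    blocks (4/4/4/3 for M=15)."""
    n_dates = len(CROSS_DATES)
    base, rem = divmod(m, n_dates)
    sizes = [base + (1 if i < rem else 0) for i in range(n_dates)]
    out: list[str] = []
    for date, size in zip(CROSS_DATES, sizes):
        out.extend([date] * size)
    return out


def simulate_design(m: int, seed: int | None = None) -> pd.DataFrame:
    """Build a complete crossing design with M 2x2 matrices.

    Returns 8*M metadata rows: per matrix one family of each cross type,
    each contributing one female and one male offspring.  The layout is
    deterministic; ``seed`` is accepted for API symmetry with the other
    simulators but unused.
    """
    if m < 1:
        raise ValidationError("number of matrices must be >= 1")
    dates = _date_blocks(m)
    rows = []
    i = 0
    for mid in range(1, m + 1):
        for cross in _CROSS_ORDER:
            for sex in ("F", "M"):
                i += 1
                rows.append(
                    {
                        "sample_id": f"S{i:03d}",
                        "matrix_id": mid,
                        "cross": cross,
                        "family_code": f"{mid}{_CELL_LETTERS[cross]}",
                        "sex": sex,
                        "cross_date": dates[mid - 1],
                    }
                )
    return validate_metadata(pd.DataFrame(rows), complete_design=True)


def _effect_magnitudes(rng, n: int, mean: float, sd: float) -> np.ndarray:
    """|log2 effect| magnitudes: normal around the mean, floored away
    from zero so every planted gene carries real signal."""
    return np.maximum(rng.normal(mean, sd, size=n), 0.25)


def simulate_counts(
    config: SimulationConfig,
    design: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw an NB count matrix and its truth table for a design.

    The log2 mean for gene g in sample j is::

        baseline_g + log2(sf_j) + beta_g * a_j + m_g * [mother=H]
        + p_g * [father=H] + s_g * [sex=F] + b_{g,date(j)} + u_{g,fam(j)}

    with ancestry dose ``a_j`` = (number of hatchery parents)/2 in
    {0, 1/2, 1} and ``u`` a per-gene-per-family normal deviate with sd
    ``family_effect_sd``.  Counts are NB with var = mu + alpha*mu^2.

    Returns ``(CountMatrix, truth)`` where truth has one row per gene:
    gene_id, gene_class in {null, ancestry, maternal, paternal, sex},
    log2_effect, and direction in {up, down, none} (sign of the effect
    for HH relative to NN, or for females on sex genes).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    design = validate_metadata(design)
    g, n = config.n_genes, len(design)

    gene_ids = [f"gene{i + 1:05d}" for i in range(g)]
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=g)
    if config.dispersion_shape is None:
        alpha = np.full(g, config.dispersion)
    else:
        scale = config.dispersion / config.dispersion_shape
        alpha = rng.gamma(config.dispersion_shape, scale, size=g)

    classes = np.array(["null"] * g, dtype=object)
    effects = np.zeros(g)
    pos = 0
    for name, count, mean_eff in (
        ("ancestry", config.n_ancestry_genes, config.ancestry_effect),
        ("maternal", config.n_maternal_genes, config.maternal_effect),
        ("paternal", config.n_paternal_genes, config.paternal_effect),
        ("sex", config.n_sex_genes, config.sex_effect),
    ):
        if count == 0:
            continue
        mags = _effect_magnitudes(rng, count, mean_eff, config.ancestry_effect_sd)
        if name == "ancestry":
            signs = np.where(rng.random(count) < config.up_fraction, 1.0, -1.0)
        else:
            signs = rng.choice([-1.0, 1.0], size=count)
        classes[pos : pos + count] = name
        effects[pos : pos + count] = signs * mags
        pos += count

    cross = design["cross"].to_numpy()
    mother_h = np.array([c[0] == "H" for c in cross], dtype=float)
    father_h = np.array([c[1] == "H" for c in cross], dtype=float)
    dose = (mother_h + father_h) / 2.0
    female = (design["sex"] == "F").to_numpy(dtype=float)

    log2_mu = baseline[:, None] + np.zeros((g, n))
    is_anc = classes == "ancestry"
    is_mat = classes == "maternal"
    is_pat = classes == "paternal"
    is_sex = classes == "sex"
    log2_mu[is_anc] += np.outer(effects[is_anc], dose)
    log2_mu[is_mat] += np.outer(effects[is_mat], mother_h)
    log2_mu[is_pat] += np.outer(effects[is_pat], father_h)
    log2_mu[is_sex] += np.outer(effects[is_sex], female)

    if config.batch_effect_sd > 0:
        dates = design["cross_date"].to_numpy()
        for date in pd.unique(dates):
            b = rng.normal(0.0, config.batch_effect_sd, size=g)
            log2_mu[:, dates == date] += b[:, None]
    if config.family_effect_sd > 0:
        fams = design["family_code"].to_numpy()
        for fam in pd.unique(fams):
            u = rng.normal(0.0, config.family_effect_sd, size=g)
            log2_mu[:, fams == fam] += u[:, None]

    size_factors = np.exp2(rng.normal(0.0, config.library_size_log2_sd, size=n))
    log2_mu += np.log2(size_factors)[None, :]

    mu = np.exp2(np.clip(log2_mu, -20.0, 25.0))
    counts = np.empty((g, n), dtype=np.int64)
    poisson_like = alpha < 1e-12
    if poisson_like.any():
        counts[poisson_like] = rng.poisson(mu[poisson_like])
    nb = ~poisson_like
    if nb.any():
        a = alpha[nb][:, None]
        counts[nb] = rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * mu[nb]))

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gene_class": classes,
            "log2_effect": effects,
            "direction": np.where(
                classes == "null", "none", np.where(effects > 0, "up", "down")
            ),
        }
    )
    return CountMatrix(gene_ids, list(design["sample_id"]), counts), truth


def simulate_genotypes(
    config: SimulationConfig,
    design: pd.DataFrame,
    n_loci: int,
    rng: np.random.Generator | None = None,
    return_parents: bool = False,
):
    """Simulate biallelic genotypes by Mendelian transmission.

    Each matrix has four parents (H mother, N mother, H father, N father)
    drawn binomially from pool allele frequencies; H and N pools differ by
    ``config.pool_freq_shift`` at every locus, producing weak HH-vs-NN
    differentiation.  Offspring receive one allele from each parent of
    their cross, so full sibs share both parents and cells of the same
    matrix share exactly one.

    With ``return_parents=True`` also returns a dict mapping
    ``(matrix_id, 'mother'|'father', 'H'|'N')`` to the parent genotype
    vector, for Mendelian-consistency checks.
    """
    if n_loci < 1:
        raise ValidationError("n_loci must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    design = validate_metadata(design)

    base = rng.uniform(0.05, 0.95, size=n_loci)
    shift = config.pool_freq_shift
    freq = {
        "H": np.clip(base + shift / 2.0, 0.01, 0.99),
        "N": np.clip(base - shift / 2.0, 0.01, 0.99),
    }

    parents: dict[tuple[int, str, str], np.ndarray] = {}
    for mid in sorted(design["matrix_id"].unique()):
        for role in ("mother", "father"):
            for origin in ("H", "N"):
                parents[(mid, role, origin)] = rng.binomial(
                    2, freq[origin], size=n_loci
                ).astype(np.int8)

    geno = np.empty((len(design), n_loci), dtype=np.int8)
    for i, row in enumerate(design.itertuples(index=False)):
        mom = parents[(row.matrix_id, "mother", row.cross[0])]
        dad = parents[(row.matrix_id, "father", row.cross[1])]
        geno[i] = rng.binomial(1, mom / 2.0) + rng.binomial(1, dad / 2.0)

    locus_ids = [f"chr1:{1000 + 10 * j}" for j in range(n_loci)]
    gm = GenotypeMatrix(list(design["sample_id"]), locus_ids, geno)
    if return_parents:
        return gm, parents
    return gm
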