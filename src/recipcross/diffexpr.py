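"""Negative-binomial GLM differential expression for count matrices.

The test is a per-gene NB log-link GLM with a fixed method-of-moments
dispersion, fit by iteratively reweighted least squares batched across
genes (all genes share one design matrix, so the normal equations can be
solved for every gene simultaneously).  The contrast coefficient is
reported as a log2 fold change with a Wald z test and Benjamini-Hochberg
FDR control.

Sign convention: ``run_de(counts, meta, "HH", "NN", ...)`` reports
positive log2 fold changes for genes expressed *higher in HH* (the first
group is the contrast, the second the reference).  Published tables that
use the opposite reference are the mirror image of this output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix, ValidationError, get_logger, validate_metadata

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "build_design",
    "fit_nb_glm",
    "bh_adjust",
    "run_de",
    "DEResultSummary",
    "sibling_correlation",
]

LN2 = np.log(2.0)
ALPHA_FLOOR = 1e-8
MAX_IRLS_ITER = 50
IRLS_TOL = 1e-8


# ---------------------------------------------------------------------------
# normalization and dispersion
# ---------------------------------------------------------------------------


def size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For genes with nonzero counts in every sample, each sample's factor is
    the median across such genes of count / (gene geometric mean).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "no gene has nonzero counts in all samples; filter low-count "
            "genes or samples before normalization"
        )
    ref = mat[all_pos].astype(float)
    log_gm = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_gm)
    s = np.median(ratios, axis=0)
    return s / np.exp(np.mean(np.log(s)))


def estimate_dispersion(
    counts: CountMatrix | np.ndarray,
    factors: np.ndarray,
    cells: np.ndarray | pd.Series | None = None,
    alpha_floor: float = ALPHA_FLOOR,
) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion on normalized counts.

    Within each covariate cell (samples sharing one combination of design
    factors), the NB moment identity var = mu + alpha*mu^2 gives a cell
    estimate; cells are pooled weighting by residual degrees of freedom:

        alpha_g = max( sum_c (n_c-1)(s2_gc - m_gc) /
                       sum_c (n_c-1) m_gc^2 , alpha_floor )

    A Poisson gene (alpha = 0) or a constant gene lands on the floor.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    g, n = mat.shape
    if n < 3:
        raise ValidationError("dispersion estimation needs at least 3 samples")
    norm = mat / factors[None, :]
    if cells is None:
        labels = np.zeros(n, dtype=int)
    else:
        labels = pd.factorize(np.asarray(cells))[0]
    num = np.zeros(g)
    den = np.zeros(g)
    for c in np.unique(labels):
        sel = labels == c
        nc = int(sel.sum())
        if nc < 2:
            continue
        sub = norm[:, sel]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += (nc - 1) * (v - m)
        den += (nc - 1) * m**2
    if not den.any():
        raise ValidationError("no covariate cell has >= 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.maximum(alpha, alpha_floor)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


def build_design(
    meta: pd.DataFrame,
    design_terms: list[str] | tuple[str, ...],
    contrast_term: str | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Build an intercept + treatment-coded design matrix.

    Each term is treated as a categorical factor with its first sorted
    level as reference.  ``contrast_term`` must be a 2-level factor (or
    ordered Categorical); its indicator column is placed last.  A
    rank-deficient design raises an error listing the aliased columns.
    """
    n = len(meta)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    terms = list(design_terms) + ([contrast_term] if contrast_term else [])
    for term in terms:
        if term not in meta.columns:
            raise ValidationError(f"design term {term!r} not in metadata")
        col = meta[term]
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels = [lv for lv in col.cat.categories if lv in set(col)]
        else:
            levels = sorted(pd.unique(col.astype(str)))
            col = col.astype(str)
        if term == contrast_term and len(levels) != 2:
            raise ValidationError(
                f"contrast term {term!r} must have exactly 2 levels, "
                f"got {levels}"
            )
        for lv in levels[1:]:
            cols.append((col == lv).to_numpy(dtype=float))
            names.append(f"{term}[{lv}]")
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(x, pivoting=True, mode="economic")
        bad = sorted(names[j] for j in piv[rank:])
        raise ValidationError(f"design matrix is rank deficient; aliased: {bad}")
    return x, names


# ---------------------------------------------------------------------------
# batched IRLS NB-GLM
# ---------------------------------------------------------------------------


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, alpha) deviance per gene; uses the Poisson limit when alpha
    is effectively zero."""
    a = np.maximum(alpha, 1e-12)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    nb_term2 = (y + 1.0 / a) * (np.log1p(a * y) - np.log1p(a * mu))
    pois_term2 = y - mu
    term2 = np.where(alpha[:, None] < 1e-7, pois_term2, nb_term2)
    return 2.0 * (term1 - term2).sum(axis=1)


def _irls_nb(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = MAX_IRLS_ITER,
    tol: float = IRLS_TOL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB log-link GLMs for all genes at once.

    y: (G, n) counts; x: (n, p) shared design; offset: (n,) log size
    factors; alpha: (G,) fixed dispersions.  Returns (beta (G, p),
    cov (G, p, p), converged (G,) bool).
    """
    g, n = y.shape
    p = x.shape[1]
    z0 = np.log(y + 0.5) - offset[None, :]
    beta, *_ = np.linalg.lstsq(x, z0.T, rcond=None)
    beta = beta.T  # (G, p)
    dev = np.full(g, np.inf)
    converged = np.zeros(g, dtype=bool)
    active = np.ones(g, dtype=bool)
    cov = np.zeros((g, p, p))
    ridge = 1e-10 * np.eye(p)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        eta = np.clip(beta[idx] @ x.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[idx, None] * mu)
        z = (eta - offset[None, :]) + (y[idx] - mu) / mu
        xtwx = np.einsum("gn,np,nq->gpq", w, x, x, optimize=True)
        xtwz = np.einsum("gn,np,gn->gp", w, x, z, optimize=True)
        try:
            new_beta = np.linalg.solve(xtwx + ridge, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        eta_new = np.clip(new_beta @ x.T + offset[None, :], -30.0, 30.0)
        dev_new = _nb_deviance(y[idx], np.exp(eta_new), alpha[idx])
        rel = np.abs(dev_new - dev[idx]) / (np.abs(dev_new) + 0.1)
        beta[idx] = new_beta
        dev[idx] = dev_new
        done = rel < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    # final covariance for every gene at its last beta
    eta = np.clip(beta @ x.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    xtwx = np.einsum("gn,np,nq->gpq", w, x, x, optimize=True)
    try:
        cov = np.linalg.inv(xtwx + ridge)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(xtwx + ridge)
    return beta, cov, converged


def fit_nb_glm(
    counts: CountMatrix,
    meta: pd.DataFrame,
    design_terms: list[str] | tuple[str, ...],
    contrast_term: str,
    factors: np.ndarray | None = None,
    alpha: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test on the contrast coefficient.

    Returns a frame indexed by gene id with columns log2_fold_change,
    lfc_se, wald_stat, p_value, p_adj, converged.  Genes with zero counts
    in every sample, or that fail IRLS convergence, get missing p-values
    and are excluded from the BH adjustment (a count is logged).
    """
    log = get_logger("recipcross.diffexpr")
    if list(counts.sample_ids) != list(meta["sample_id"]):
        meta = meta.set_index("sample_id").loc[counts.sample_ids].reset_index()
    x, _names = build_design(meta, design_terms, contrast_term)
    if factors is None:
        factors = size_factors(counts)
    y = counts.counts.astype(float)
    if alpha is None:
        cell_cols = [c for c in (*design_terms, contrast_term)]
        cells = meta[cell_cols].astype(str).agg("|".join, axis=1)
        alpha = estimate_dispersion(counts, factors, cells)

    g = y.shape[0]
    testable = y.sum(axis=1) > 0
    beta = np.full((g, x.shape[1]), np.nan)
    se = np.full(g, np.nan)
    converged = np.zeros(g, dtype=bool)
    if testable.any():
        b, cov, conv = _irls_nb(
            y[testable], x, np.log(factors), alpha[testable]
        )
        beta[testable] = b
        se_t = np.sqrt(np.maximum(cov[:, -1, -1], 0.0))
        # finite-sample df correction: information-matrix SEs ignore the
        # p estimated mean parameters, leaving Wald z over-dispersed by
        # ~sqrt(n/(n-p)) under the null
        n_obs, n_par = x.shape
        if n_obs > n_par:
            se_t = se_t * np.sqrt(n_obs / (n_obs - n_par))
        se[testable] = se_t
        converged[testable] = conv

    n_skipped = int((~testable).sum())
    n_failed = int((testable & ~converged).sum())
    if n_skipped:
        log.info("%d gene(s) with all-zero counts not tested", n_skipped)
    if n_failed:
        log.info("%d gene(s) failed IRLS convergence; excluded from FDR", n_failed)

    lfc = beta[:, -1] / LN2
    lfc_se = se / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = beta[:, -1] / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p[~converged] = np.nan
    res = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "lfc_se": lfc_se,
            "wald_stat": wald,
            "p_value": p,
            "p_adj": bh_adjust(p),
            "converged": converged,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
    return res


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Missing values (NaN) are passed through and do not count toward the
    number of tests.  Output is elementwise >= input and monotone
    nondecreasing in p rank.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    vals = p[ok]
    if ((vals < 0) | (vals > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# the full DE pipeline
# ---------------------------------------------------------------------------


@dataclass
class DEResultSummary:
    """A DE run: the per-gene table plus DEG counts at the FDR cutoff."""

    table: pd.DataFrame
    fdr: float
    n_deg: int
    n_up: int  # higher in group A (the contrast group)
    n_down: int
    group_a: list[str] = field(default_factory=list)
    group_b: list[str] = field(default_factory=list)


def _resolve_group(meta: pd.DataFrame, group) -> list[str]:
    """A group may be a cross-type label ('HH') or a list of sample ids."""
    if isinstance(group, str):
        ids = meta.loc[meta["cross"] == group, "sample_id"].tolist()
        if not ids:
            raise ValidationError(f"no samples with cross type {group!r}")
        return ids
    return list(group)


def run_de(
    counts: CountMatrix,
    meta: pd.DataFrame,
    group_a,
    group_b,
    design_terms: tuple[str, ...] = ("cross_date", "sex"),
    fdr: float = 0.05,
) -> DEResultSummary:
    """Differential expression between two disjoint sample groups.

    Groups may be cross-type labels or explicit sample-id lists; group B
    is the reference, so positive log2 fold changes mean higher
    expression in group A.  Covariates in ``design_terms`` are kept in
    the fitted model.
    """
    meta = validate_metadata(meta)
    ids_a = _resolve_group(meta, group_a)
    ids_b = _resolve_group(meta, group_b)
    if set(ids_a) & set(ids_b):
        raise ValidationError("groups must be disjoint")
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    keep = ids_a + ids_b
    sub_counts = counts.subset_samples(keep)
    sub_meta = meta.set_index("sample_id").loc[keep].reset_index()
    sub_meta["group"] = pd.Categorical(
        ["A" if s in set(ids_a) else "B" for s in keep], categories=["B", "A"]
    )
    # drop covariates that are constant on this subset
    terms = tuple(t for t in design_terms if sub_meta[t].nunique() > 1)
    table = fit_nb_glm(sub_counts, sub_meta, terms, "group")
    sig = table["p_adj"] < fdr
    n_up = int((sig & (table["log2_fold_change"] > 0)).sum())
    n_down = int((sig & (table["log2_fold_change"] < 0)).sum())
    return DEResultSummary(
        table=table,
        fdr=fdr,
        n_deg=int(sig.sum()),
        n_up=n_up,
        n_down=n_down,
        group_a=ids_a,
        group_b=ids_b,
    )


# ---------------------------------------------------------------------------
# sibling correlation
# ---------------------------------------------------------------------------


def sibling_correlation(
    counts: CountMatrix,
    meta: pd.DataFrame,
    factors: np.ndarray | None = None,
    design_terms: tuple[str, ...] = ("cross_date", "sex", "cross"),
    trim: float = 0.1,
) -> float:
    """Consensus within-family correlation of log normalized counts.

    Per gene, log2(normalized count + 1) values are residualized on the
    design covariates, and the correlation between the two siblings of
    each family is estimated as the one-way intraclass correlation across
    families.  The consensus is the inverse Fisher-z of the trimmed mean
    (``trim`` cut from each tail) of the per-gene Fisher-z values.
    """
    meta = validate_metadata(meta)
    if list(counts.sample_ids) != list(meta["sample_id"]):
        meta = meta.set_index("sample_id").loc[counts.sample_ids].reset_index()
    fam_sizes = meta.groupby("family_code")["sample_id"].count()
    fams = fam_sizes[fam_sizes == 2].index.tolist()
    if len(fams) < 3:
        raise ValidationError(
            "sibling correlation needs at least 3 families with 2 offspring"
        )
    if factors is None:
        factors = size_factors(counts)
    y = np.log2(counts.counts / factors[None, :] + 1.0)
    terms = tuple(t for t in design_terms if meta[t].nunique() > 1)
    x, _ = build_design(meta, terms)
    # project out covariates: residual = Y (I - H)
    h = x @ np.linalg.pinv(x)
    resid = y - y @ h.T

    sid_to_col = {s: i for i, s in enumerate(counts.sample_ids)}
    pairs = np.array(
        [
            [sid_to_col[s] for s in meta.loc[meta["family_code"] == f, "sample_id"]]
            for f in fams
        ]
    )  # (k, 2)
    a = resid[:, pairs[:, 0]]
    b = resid[:, pairs[:, 1]]
    # one-way ANOVA intraclass correlation with 2 members per family
    grand = (a + b) / 2.0
    gm = grand.mean(axis=1, keepdims=True)
    k = len(fams)
    msb = 2.0 * ((grand - gm) ** 2).sum(axis=1) / (k - 1)
    msw = ((a - grand) ** 2 + (b - grand) ** 2).sum(axis=1) / k
    denom = msb + msw
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (msb - msw) / denom, np.nan)
    r = r[~np.isnan(r)]
    if r.size == 0:
        raise ValidationError("no informative genes for sibling correlation")
    z = np.arctanh(np.clip(r, -0.9999, 0.9999))
    consensus_z = stats.trim_mean(z, proportiontocut=trim)
    return float(np.tanh(consensus_z))
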