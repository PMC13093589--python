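"""Inheritance-mode decomposition for reciprocal-cross DEGs.

Given a DEG's standardized log expression in the four cross types, the
heterozygous crosses discriminate three inheritance models:

* additive — HN and NH both sit at the midpoint of HH and NN (expression
  tracks total hatchery ancestry);
* maternal — offspring sharing a mother match: HN tracks HH (hatchery
  mother) and NH tracks NN (natural mother);
* paternal — the mirror: HN tracks NN and NH tracks HH.

Each model predicts the pair (HN, NH) from the observed (HH, NN); the
per-gene discrepancy score is the SE-weighted squared deviation of the
observed heterozygous-cross means from those predictions, and the call
is the best-scoring model unless the top two scores are within a tie
tolerance (then ``ambiguous``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix, CROSS_TYPES, ValidationError, validate_metadata
from .diffexpr import size_factors

__all__ = [
    "standardized_log_values",
    "standardized_log_means",
    "visual_shift",
    "classify_mode",
    "mode_summary",
    "direction_bias_test",
    "DirectionBiasResult",
]

MODES = ("additive", "maternal", "paternal")


def standardized_log_values(
    counts: CountMatrix, factors: np.ndarray | None = None
) -> pd.DataFrame:
    """log2(size-factor normalized count + 1) per gene and sample."""
    if factors is None:
        factors = size_factors(counts)
    vals = np.log2(counts.counts / factors[None, :] + 1.0)
    return pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids)


def standardized_log_means(
    counts: CountMatrix,
    meta: pd.DataFrame,
    factors: np.ndarray | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene mean and SE of standardized log counts in each cross group.

    Returns a frame indexed by gene with columns ``mean_XX``/``se_XX``
    for each cross type and ``direction`` in {up_in_HH, up_in_NN, tie}
    from the sign of mean_HH - mean_NN.
    """
    meta = validate_metadata(meta)
    vals = standardized_log_values(counts, factors)
    if genes is not None:
        missing = set(genes) - set(vals.index)
        if missing:
            raise ValidationError(f"genes not in count matrix: {sorted(missing)[:5]}")
        vals = vals.loc[genes]
    out = pd.DataFrame(index=vals.index)
    for cross in CROSS_TYPES:
        ids = meta.loc[meta["cross"] == cross, "sample_id"].tolist()
        if len(ids) < 2:
            raise ValidationError(f"cross group {cross} has fewer than 2 samples")
        sub = vals[ids].to_numpy()
        out[f"mean_{cross}"] = sub.mean(axis=1)
        out[f"se_{cross}"] = sub.std(axis=1, ddof=1) / np.sqrt(len(ids))
    diff = out["mean_HH"] - out["mean_NN"]
    out["direction"] = np.select(
        [diff > 0, diff < 0], ["up_in_HH", "up_in_NN"], default="tie"
    )
    out.index.name = "gene_id"
    return out


def visual_shift(
    values: pd.DataFrame, meta: pd.DataFrame, genes: list[str] | None = None
) -> pd.DataFrame:
    """Shift every gene so all HH group means coincide (plotting aid).

    Each gene's values (all samples) are shifted by the difference
    between the gene set's grand HH mean and that gene's HH mean.  The
    shift is a per-gene constant, so within-gene group contrasts are
    preserved exactly.
    """
    meta = validate_metadata(meta)
    if genes is not None:
        values = values.loc[genes]
    hh_ids = meta.loc[meta["cross"] == "HH", "sample_id"].tolist()
    gene_hh_means = values[hh_ids].mean(axis=1)
    grand = gene_hh_means.mean()
    return values.add(grand - gene_hh_means, axis=0)


def classify_mode(
    group_means: pd.DataFrame, tie_tol: float = 0.10, tie_margin: float = 6.0
) -> pd.DataFrame:
    """Score each gene against the additive/maternal/paternal models.

    Predictions for (HN, NH) given observed (HH, NN): additive
    (mid, mid) with mid = (HH+NN)/2; maternal (HH, NN); paternal
    (NN, HH).  Score = sum over the two heterozygous crosses of
    (observed - predicted)^2 / SE^2, i.e. a 2-df chi-square-scale
    discrepancy.  The call is the argmin model, declared ``ambiguous``
    when the runner-up is within ``tie_tol`` (relative) of the best OR
    within ``tie_margin`` score units absolutely — the absolute margin
    keeps low-signal genes (where all three models fit comparably, e.g.
    null genes with HH ~ NN) from receiving arbitrary calls.
    """
    gm = group_means
    se_hn = gm["se_HN"].to_numpy()
    se_nh = gm["se_NH"].to_numpy()
    if (se_hn <= 0).any() or (se_nh <= 0).any():
        raise ValidationError("zero or negative SE for a heterozygous cross group")
    hh = gm["mean_HH"].to_numpy()
    nn = gm["mean_NN"].to_numpy()
    hn = gm["mean_HN"].to_numpy()
    nh = gm["mean_NH"].to_numpy()
    mid = (hh + nn) / 2.0
    preds = {
        "additive": (mid, mid),
        "maternal": (hh, nn),
        "paternal": (nn, hh),
    }
    scores = {
        mode: ((hn - phn) / se_hn) ** 2 + ((nh - pnh) / se_nh) ** 2
        for mode, (phn, pnh) in preds.items()
    }
    score_mat = np.column_stack([scores[m] for m in MODES])
    order = np.argsort(score_mat, axis=1)
    best = score_mat[np.arange(len(gm)), order[:, 0]]
    second = score_mat[np.arange(len(gm)), order[:, 1]]
    calls = np.array(MODES, dtype=object)[order[:, 0]]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_tie = np.where(best > 0, second / best < 1.0 + tie_tol, second <= 0)
    ambiguous = rel_tie | (second - best < tie_margin)
    calls[ambiguous] = "ambiguous"
    out = pd.DataFrame(
        {
            "call": calls,
            "score_additive": scores["additive"],
            "score_maternal": scores["maternal"],
            "score_paternal": scores["paternal"],
        },
        index=gm.index,
    )
    if "direction" in gm.columns:
        out["direction"] = gm["direction"]
    return out


def mode_summary(calls: pd.DataFrame) -> dict:
    """Contingency of inheritance call by direction and additive fraction.

    The additive fraction is computed over unambiguous calls; an input
    with no unambiguous call is an error.
    """
    if calls.empty:
        raise ValidationError("empty inheritance-call table")
    direction = calls.get("direction", pd.Series("all", index=calls.index))
    table = pd.crosstab(calls["call"], direction)
    informative = calls[calls["call"] != "ambiguous"]
    if informative.empty:
        raise ValidationError("no unambiguous inheritance calls")
    frac_additive = float((informative["call"] == "additive").mean())
    return {
        "contingency": table,
        "fraction_additive": frac_additive,
        "n_ambiguous": int((calls["call"] == "ambiguous").sum()),
    }


@dataclass
class DirectionBiasResult:
    n_up: int
    n_down: int
    chi2: float
    chi2_p: float
    binom_p: float


def direction_bias_test(n_up: int, n_down: int) -> DirectionBiasResult:
    """Test an up/down DEG split against a 50:50 expectation.

    Reports the 1-df goodness-of-fit chi-square and the exact two-sided
    binomial p-value.
    """
    if n_up < 0 or n_down < 0 or n_up + n_down < 1:
        raise ValidationError("need a positive total DEG count")
    total = n_up + n_down
    expected = total / 2.0
    chi2 = (n_up - expected) ** 2 / expected + (n_down - expected) ** 2 / expected
    chi2_p = float(stats.chi2.sf(chi2, df=1))
    binom_p = float(stats.binomtest(n_up, total, 0.5).pvalue)
    return DirectionBiasResult(n_up, n_down, float(chi2), chi2_p, binom_p)
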