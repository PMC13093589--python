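"""Constrained reshuffling procedures for DEG-count inference.

Two complementary randomizations assess whether the HH-vs-NN DEG count
could arise by chance:

* an *ancestry gradient*: offspring are repeatedly split into two groups
  of equal size where one group contains exactly N HH fish (and no NN)
  and the other exactly N NN fish (and no HH), the remaining slots being
  filled by reciprocal-cross (HN/NH) offspring.  As N grows, so does the
  ancestry contrast between the groups, and with it the expected DEG
  count; at N = group size the partition is the empirical HH-vs-NN split
  itself.
* a *conservative null permutation*: only HH and NN offspring are
  shuffled, ignoring their cross labels, into two equal groups;
  the empirical p-value is the fraction of reshuffles producing at least
  as many DEGs as the observed split.

Samples are canonically sorted by id before any draw, so a seed produces
the same partitions regardless of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountMatrix, ValidationError, validate_metadata
from .diffexpr import run_de

__all__ = [
    "constrained_partition",
    "ancestry_gradient",
    "null_permutation",
    "GradientResult",
    "NullPermResult",
    "DEFAULT_CONSTRAINTS",
]

DEFAULT_CONSTRAINTS = (1, 5, 10, 15, 20, 25, 30)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _cross_ids(meta: pd.DataFrame) -> dict[str, list[str]]:
    return {
        c: sorted(meta.loc[meta["cross"] == c, "sample_id"])
        for c in ("HH", "HN", "NH", "NN")
    }


def constrained_partition(
    meta: pd.DataFrame,
    n: int,
    rng,
    with_replacement: bool = False,
) -> tuple[list[str], list[str]]:
    """Draw one constrained two-group partition.

    Group A gets exactly ``n`` HH offspring and no NN; group B exactly
    ``n`` NN and no HH; the remaining slots of each group are filled with
    HN/NH offspring, by default sampled without replacement across both
    groups (``with_replacement=True`` samples each group's filler
    independently with replacement).  Group size equals the per-type
    sample count of a complete design (30 for M=15).
    """
    rng = _as_rng(rng)
    meta = validate_metadata(meta)
    ids = _cross_ids(meta)
    size = len(ids["HH"])
    if len(ids["NN"]) != size:
        raise ValidationError("HH and NN sample counts differ; incomplete design")
    if not 1 <= n <= size:
        raise ValidationError(f"constraint N={n} outside [1, {size}]")
    pool = sorted(ids["HN"] + ids["NH"])
    fill = size - n
    if not with_replacement and 2 * fill > len(pool):
        raise ValidationError(
            f"need {2 * fill} reciprocal-cross fillers, pool has {len(pool)}"
        )
    group_a = list(rng.choice(ids["HH"], size=n, replace=False))
    group_b = list(rng.choice(ids["NN"], size=n, replace=False))
    if fill:
        if with_replacement:
            group_a += list(rng.choice(pool, size=fill, replace=True))
            group_b += list(rng.choice(pool, size=fill, replace=True))
        else:
            drawn = rng.choice(pool, size=2 * fill, replace=False)
            group_a += list(drawn[:fill])
            group_b += list(drawn[fill:])
    return group_a, group_b


@dataclass
class GradientResult:
    """Mean DEG counts (with percentile 95% CIs) per constraint level."""

    summary: pd.DataFrame  # index N; columns mean, ci_low, ci_high, n_replicates
    replicate_counts: dict[int, np.ndarray]
    replicate_up_counts: dict[int, np.ndarray]
    fdr: float


def ancestry_gradient(
    counts: CountMatrix,
    meta: pd.DataFrame,
    constraints: tuple[int, ...] = DEFAULT_CONSTRAINTS,
    replicates: int = 1000,
    fdr: float = 0.05,
    rng=None,
    design_terms: tuple[str, ...] = ("cross_date", "sex"),
    with_replacement: bool = False,
) -> GradientResult:
    """DEG counts across an increasing ancestry-contrast gradient.

    For each constraint level N, ``replicates`` constrained partitions
    are drawn and differential expression is run on each (model:
    covariates + group).  At the maximum N every partition is the
    identical empirical HH-vs-NN split, so the replicate distribution is
    degenerate (zero CI width) and it is computed once.
    """
    if replicates < 2:
        raise ValidationError("need at least 2 replicates")
    rng = _as_rng(rng)
    meta = validate_metadata(meta)
    size = (meta["cross"] == "HH").sum()
    rows = []
    rep_counts: dict[int, np.ndarray] = {}
    rep_up: dict[int, np.ndarray] = {}
    for n in constraints:
        if n == size:
            res = run_de(counts, meta, "HH", "NN", design_terms, fdr)
            arr = np.full(replicates, res.n_deg)
            arr_up = np.full(replicates, res.n_up)
        else:
            arr = np.empty(replicates, dtype=int)
            arr_up = np.empty(replicates, dtype=int)
            for r in range(replicates):
                ga, gb = constrained_partition(meta, n, rng, with_replacement)
                res = run_de(counts, meta, ga, gb, design_terms, fdr)
                arr[r] = res.n_deg
                arr_up[r] = res.n_up
        rep_counts[n] = arr
        rep_up[n] = arr_up
        lo, hi = np.percentile(arr, [2.5, 97.5])
        rows.append(
            {
                "N": n,
                "mean": float(arr.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_replicates": replicates,
            }
        )
    summary = pd.DataFrame(rows).set_index("N")
    return GradientResult(summary, rep_counts, rep_up, fdr)


@dataclass
class NullPermResult:
    """Permutation null for the HH-vs-NN DEG count.

    ``p_total``/``p_up`` use the add-one convention (1+b)/(R+1) by
    default, which can never be zero; ``p_total_plain`` is the b/R
    variant.  ``p_total_smoothed``/``p_up_smoothed`` are the randomized
    (tie-smoothed) permutation p-values, exactly Uniform(0,1) under the
    null, intended for calibration diagnostics.
    """

    observed_total: int
    observed_up: int
    replicate_counts: np.ndarray
    replicate_up_counts: np.ndarray
    p_total: float
    p_up: float
    p_total_plain: float
    p_up_plain: float
    p_total_smoothed: float
    p_up_smoothed: float
    fdr: float = 0.05


def _perm_pvalues(obs: int, reps: np.ndarray, u: float) -> tuple[float, float, float]:
    r = reps.size
    b = int((reps >= obs).sum())
    greater = int((reps > obs).sum())
    ties = b - greater
    add_one = (1 + b) / (r + 1)
    plain = b / r
    smoothed = (greater + u * (1 + ties)) / (r + 1)
    return add_one, plain, smoothed


def null_permutation(
    counts: CountMatrix,
    meta: pd.DataFrame,
    replicates: int = 1000,
    fdr: float = 0.05,
    rng=None,
    design_terms: tuple[str, ...] = ("cross_date", "sex"),
) -> NullPermResult:
    """Conservative permutation of HH/NN labels.

    HH and NN offspring are pooled, shuffled without replacement into
    two equal groups, and differential expression is run per shuffle.
    The empirical p-value for the observed totals is
    (1 + #{replicate >= observed}) / (R + 1).
    """
    if replicates < 2:
        raise ValidationError("need at least 2 replicates")
    rng = _as_rng(rng)
    meta = validate_metadata(meta)
    ids = _cross_ids(meta)
    pool = sorted(ids["HH"] + ids["NN"])
    if len(pool) % 2:
        raise ValidationError("pooled HH+NN sample count must be even")
    half = len(pool) // 2

    observed = run_de(counts, meta, "HH", "NN", design_terms, fdr)
    rep_counts = np.empty(replicates, dtype=int)
    rep_up = np.empty(replicates, dtype=int)
    for r in range(replicates):
        perm = rng.permutation(pool)
        res = run_de(counts, meta, list(perm[:half]), list(perm[half:]), design_terms, fdr)
        rep_counts[r] = res.n_deg
        rep_up[r] = res.n_up
    u_total, u_up = rng.random(2)
    p_total, p_total_plain, p_total_sm = _perm_pvalues(
        observed.n_deg, rep_counts, u_total
    )
    p_up, p_up_plain, p_up_sm = _perm_pvalues(observed.n_up, rep_up, u_up)
    return NullPermResult(
        observed_total=observed.n_deg,
        observed_up=observed.n_up,
        replicate_counts=rep_counts,
        replicate_up_counts=rep_up,
        p_total=p_total,
        p_up=p_up,
        p_total_plain=p_total_plain,
        p_up_plain=p_up_plain,
        p_total_smoothed=p_total_sm,
        p_up_smoothed=p_up_sm,
        fdr=fdr,
    )
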