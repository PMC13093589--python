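"""GO-term summarization: k-means on 2-D semantic coordinates.

Consumes a term table produced upstream by semantic-similarity reduction
(one row per GO term with the number of distinct DEGs carrying it and
its 2-D semantic-space coordinates).  Terms are clustered by k-means on
the coordinates, k chosen from the knee of the within-cluster
sum-of-squares curve; each cluster is named by the member term shared by
the most DEGs, and labeled with its most frequent word.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core_io import ValidationError

__all__ = [
    "choose_k",
    "cluster_terms",
    "word_labels",
    "ClusterSolution",
    "STOP_WORDS",
]

#: function words excluded from word-frequency labeling
STOP_WORDS = frozenset({"of", "to", "in", "the", "and", "process", "regulation"})

DEFAULT_K_RANGE = tuple(range(1, 16))


def _wss_curve(points: np.ndarray, k_range, seed: int) -> dict[int, float]:
    wss = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(points)
        wss[k] = float(km.inertia_)
    return wss


def choose_k(
    points: np.ndarray,
    k_range: tuple[int, ...] = DEFAULT_K_RANGE,
    seed: int = 0,
) -> int:
    """Pick k from the knee of the within-cluster sum-of-squares curve.

    The knee is the k whose (k, log WSS) point lies farthest below the
    chord joining the curve's endpoints, after normalizing both axes to
    [0, 1].  The log scale makes the sharp WSS drop at the true cluster
    count dominate the gradual decline before it, and leaves the choice
    invariant to rescaling the coordinates (which multiplies every WSS
    by a constant).  Identical points degenerate to k = 1.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValidationError("points must be a 2-D array")
    if np.allclose(points, points[0]):
        return 1
    k_range = sorted(k_range)
    if len(points) < max(k_range) + 1:
        raise ValidationError(
            f"need at least {max(k_range) + 1} points for k_range up to {max(k_range)}"
        )
    wss = _wss_curve(points, k_range, seed)
    ks = np.array(k_range, dtype=float)
    ws = np.array([wss[k] for k in k_range])
    # relative floor keeps the log finite and the rule scale-invariant
    ws = np.log(np.maximum(ws, 1e-12 * ws[0] + 1e-300))
    kx = (ks - ks[0]) / (ks[-1] - ks[0])
    span = ws[0] - ws[-1]
    wy = (ws - ws[-1]) / span if span > 0 else np.zeros_like(ws)
    # perpendicular distance from the chord joining the endpoints
    chord = np.array([1.0, wy[-1] - wy[0]])
    chord /= np.linalg.norm(chord)
    rel = np.column_stack([kx - 0.0, wy - wy[0]])
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    return int(k_range[int(np.argmax(dist))])


def word_labels(cluster_terms: pd.DataFrame, n_top: int = 6) -> tuple[str, pd.DataFrame]:
    """Dominant word of a cluster plus its most-shared terms.

    Term names are lowercased and split on non-letter characters; stop
    words are excluded.  The dominant word is the modal token (ties
    broken alphabetically).  The returned frame holds the ``n_top``
    member terms by DEG count (fewer if the cluster is smaller).
    """
    if cluster_terms.empty:
        raise ValidationError("empty cluster")
    tokens: Counter = Counter()
    for name in cluster_terms["name"]:
        for tok in re.split(r"[^a-z]+", str(name).lower()):
            if tok and tok not in STOP_WORDS:
                tokens[tok] += 1
    if tokens:
        top_count = max(tokens.values())
        dominant = min(w for w, c in tokens.items() if c == top_count)
    else:
        dominant = ""
    labeled = cluster_terms.sort_values(
        ["count", "go_id"], ascending=[False, True]
    ).head(n_top)
    return dominant, labeled


@dataclass
class ClusterSolution:
    """A k-means partition of the term table.

    ``assignments`` maps go_id -> cluster id; ``clusters`` has one row
    per cluster: cluster id, size, name (the member GO term carried by
    the most DEGs), its count, and the cluster's dominant word.
    ``wss`` is the within-cluster sum of squares of the chosen solution.
    """

    k: int
    assignments: pd.Series
    clusters: pd.DataFrame
    top_terms: dict[int, pd.DataFrame]
    wss: float


def cluster_terms(
    terms: pd.DataFrame, k: int, seed: int = 0, n_top: int = 6
) -> ClusterSolution:
    """k-means clustering of GO terms on their semantic coordinates.

    Terms are canonically sorted by go_id before fitting, so the same
    seed yields the same solution regardless of input row order.  The
    best of 10 seeded restarts (by WSS) is kept.  Cluster names are the
    member term with the largest DEG count, ties broken alphabetically
    by GO id.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(terms):
        raise ValidationError(f"k={k} exceeds the {len(terms)} available terms")
    terms = terms.sort_values("go_id").reset_index(drop=True)
    pts = terms[["pc1", "pc2"]].to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pts)
    labels = km.labels_
    assignments = pd.Series(labels, index=terms["go_id"], name="cluster")
    rows = []
    top_terms: dict[int, pd.DataFrame] = {}
    for c in range(k):
        members = terms[labels == c]
        dominant, labeled = word_labels(members, n_top=n_top)
        name_row = members.sort_values(["count", "go_id"], ascending=[False, True]).iloc[0]
        top_terms[c] = labeled.reset_index(drop=True)
        rows.append(
            {
                "cluster": c,
                "n_terms": len(members),
                "name": name_row["name"],
                "name_go_id": name_row["go_id"],
                "name_count": int(name_row["count"]),
                "dominant_word": dominant,
            }
        )
    clusters = pd.DataFrame(rows).set_index("cluster")
    return ClusterSolution(
        k=k,
        assignments=assignments,
        clusters=clusters,
        top_terms=top_terms,
        wss=float(km.inertia_),
    )
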