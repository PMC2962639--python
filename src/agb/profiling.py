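"""Composite scores, alignment-profile matrices, similarity, ROC, dendrograms.

Each query is encoded against an M-profile library as a vector of
non-negative composite scores (its *alignment profile*); vectors are then
compared by Pearson correlation or Euclidean distance, ranked for top-k ROC
evaluation against fold-group labels, and clustered into dendrograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .adaptive import FinalAlignment, SearchParams, adaptive_search
from .seqio import ProteinSequence, ScoringProfile


@dataclass
class AlignmentProfile:
    """One query's length-M vector of composite scores."""

    query_id: str
    values: np.ndarray
    column_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.column_ids):
            raise ValueError("profile vector length does not match column ids")
        if (self.values < 0).any():
            raise ValueError("composite scores must be non-negative")


@dataclass(frozen=True)
class RocPoint:
    k: int
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0


def composite_score(survivors: Sequence[FinalAlignment]) -> float:
    """(number of survivors) x (mean identity) x (max coverage).

    Identity and coverage enter as fractions in [0, 1], so the score is 0
    with no survivors and never exceeds the survivor count.
    """
    if not survivors:
        return 0.0
    count = len(survivors)
    mean_id = sum(fa.identity_pct for fa in survivors) / count / 100.0
    max_cov = max(fa.coverage_pct for fa in survivors) / 100.0
    return count * mean_id * max_cov


def build_profile_matrix(
    queries: Sequence[ProteinSequence],
    profiles: Sequence[ScoringProfile],
    params: SearchParams = SearchParams(),
) -> pd.DataFrame:
    """N x M matrix of composite scores; rows = query ids, columns = profile
    ids.  Deterministic for fixed parameters (no randomness in the search)."""
    if not queries or not profiles:
        raise ValueError("need at least one query and one profile")
    data = np.zeros((len(queries), len(profiles)))
    for i, query in enumerate(queries):
        for j, prof in enumerate(profiles):
            res = adaptive_search(query, prof, params)
            data[i, j] = composite_score(res.alignments)
    return pd.DataFrame(data, index=[s.id for s in queries], columns=[p.id for p in profiles])


def profile_similarity(a: np.ndarray, b: np.ndarray, metric: str = "pearson") -> Optional[float]:
    """Pearson correlation (None when either vector is constant — reported
    as missing, not 0) or Euclidean distance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if metric == "euclidean":
        return float(np.linalg.norm(a - b))
    if metric == "pearson":
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return None
        return float(np.corrcoef(a, b)[0, 1])
    raise ValueError(f"unknown metric {metric!r}")


def similarity_rankings(
    matrix: pd.DataFrame, metric: str = "pearson"
) -> dict[str, list[str]]:
    """Per query, the other queries ordered by decreasing similarity
    (increasing distance for euclidean).  Pairs with undefined Pearson
    correlation are excluded from that query's ranking; similarity ties are
    broken by query id for determinism."""
    ids = list(matrix.index)
    vals = matrix.to_numpy(dtype=float)
    out: dict[str, list[str]] = {}
    for i, qid in enumerate(ids):
        scored = []
        for j, other in enumerate(ids):
            if i == j:
                continue
            s = profile_similarity(vals[i], vals[j], metric)
            if s is None:
                continue
            key = -s if metric == "pearson" else s
            scored.append((key, other))
        scored.sort()
        out[qid] = [other for _, other in scored]
    return out


def roc_curve(
    rankings: dict[str, list[str]],
    labels: dict[str, str],
    k_max: int = 40,
) -> list[RocPoint]:
    """Top-k ROC points, k = 1..k_max.

    For each query the top-k ranked sequences are predicted positives; the
    true positives are the other members of its fold group.  Counts are
    pooled over queries whose group has at least one other member (a
    singleton query contributes no positives and is skipped), so
    sensitivity = TP/(TP+FN) and FPR = FP/(FP+TN) hold exactly on the
    pooled counts; with equal group sizes this equals the per-query
    average.  Both rates are nondecreasing in k.
    """
    points = []
    for k in range(1, k_max + 1):
        tp = fp = tn = fn = 0
        for qid, ranked in rankings.items():
            pos = {o for o in ranked if labels.get(o) == labels.get(qid)}
            if not pos:
                continue
            top = ranked[:k]
            q_tp = sum(1 for o in top if o in pos)
            q_fp = len(top) - q_tp
            tp += q_tp
            fp += q_fp
            fn += len(pos) - q_tp
            tn += (len(ranked) - len(pos)) - q_fp
        points.append(RocPoint(k, tp, fp, tn, fn))
    return points


def roc_points_frame(points: Iterable[RocPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "k": p.k, "TP": p.tp, "FP": p.fp, "TN": p.tn, "FN": p.fn,
                "sensitivity": p.sensitivity, "fpr": p.fpr,
            }
            for p in points
        ]
    )


def dendrogram(matrix: pd.DataFrame, metric: str = "pearson") -> TreeNode:
    """Average-linkage hierarchical clustering of the alignment profiles.

    Pearson distance is 1 - r; constant rows make that undefined and raise
    an error naming the offending rows.  Returns a scikit-bio tree with
    branch lengths (write it with :func:`agb.seqio.write_newick`).
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two profiles to cluster")
    vals = matrix.to_numpy(dtype=float)
    ids = [str(i) for i in matrix.index]
    if metric == "pearson":
        flat = np.ptp(vals, axis=1) == 0
        if flat.any():
            bad = [ids[i] for i in np.nonzero(flat)[0]]
            raise ValueError(f"constant alignment profile rows (Pearson undefined): {bad}")
        dist = 1.0 - np.corrcoef(vals)
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        cond = squareform(dist, checks=False)
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist

        cond = pdist(vals, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    Z = linkage(cond, method="average")
    return TreeNode.from_linkage_matrix(Z, ids)
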