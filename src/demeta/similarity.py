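"""Disease-similarity profiling: signed log-p variation scores, rank correlation, clustering.

Each study is summarised by its expression variation profile, the per-gene
score sign(t_j) * log(p_j) combining the direction and strength of
differential expression.  Profiles are compared by Kendall tau-b or Spearman
rank correlation, and the studies are clustered agglomeratively on the
dissimilarity 1 - r with average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .meta import DEFAULT_P_FLOOR, clamp_p

METHODS = ("kendall", "spearman")


@dataclass
class VariationProfile:
    study_id: str
    scores: pd.Series  # gene-indexed, canonical gene order


@dataclass
class CorrelationMatrix:
    study_ids: list[str]
    method: str
    values: pd.DataFrame  # square, symmetric, unit diagonal

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be square and symmetric")


@dataclass
class Dendrogram:
    """Agglomerative merge history over study leaves.

    ``merges`` lists (members_a, members_b, height) with members given as
    sorted tuples of study ids; ``linkage_matrix`` is the scipy encoding over
    ``labels`` (lexicographically sorted leaf order).  ``metadata`` records the
    distance and linkage choices.
    """

    labels: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    linkage_matrix: np.ndarray
    metadata: dict = field(default_factory=dict)


def variation_profile(
    de_result: pd.DataFrame,
    study_id: str,
    floor: float = DEFAULT_P_FLOOR,
    negate: bool = False,
) -> VariationProfile:
    """Per-gene expression variation score sign(t) * ln(p), p clamped to [floor, 1].

    With ``negate=True`` the -log convention sign(t) * (-ln p) is emitted
    instead (positive for significant up-regulation); default is the plain
    sign(t) * ln(p) form.
    """
    t = de_result["t"].to_numpy()
    p = clamp_p(de_result["p"].to_numpy(), floor)
    scores = np.sign(t) * np.log(p)
    if negate:
        scores = -scores
    return VariationProfile(study_id, pd.Series(scores, index=de_result.index))


def correlation_matrix(
    profiles: Sequence[VariationProfile], method: str = "kendall"
) -> CorrelationMatrix:
    """Pairwise Kendall tau-b or Spearman rho between variation profiles."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    genes = list(profiles[0].scores.index)
    if len(genes) < 3:
        raise ValueError("need at least three genes")
    for pr in profiles[1:]:
        if list(pr.scores.index) != genes:
            raise ValueError(f"{pr.study_id}: gene order differs across profiles")
    frame = pd.DataFrame({pr.study_id: pr.scores.to_numpy() for pr in profiles})
    corr = frame.corr(method=method)  # pandas kendall is tau-b
    np.fill_diagonal(corr.values, 1.0)
    return CorrelationMatrix(list(frame.columns), method, corr)


def cluster_studies(corr: CorrelationMatrix) -> Dendrogram:
    """Average-linkage agglomerative clustering on the dissimilarity 1 - r.

    Leaves are ordered lexicographically before clustering so that merge order
    is deterministic under ties (smallest member wins).
    """
    labels = sorted(corr.study_ids)
    r = corr.values.loc[labels, labels].to_numpy()
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)
    z = linkage(squareform(d, checks=False), method="average")

    members: dict[int, tuple[str, ...]] = {i: (lab,) for i, lab in enumerate(labels)}
    merges = []
    for i, (a, b, height, _) in enumerate(z):
        ma, mb = members[int(a)], members[int(b)]
        merges.append((ma, mb, float(height)))
        members[len(labels) + i] = tuple(sorted(ma + mb))
    return Dendrogram(
        labels=labels,
        merges=merges,
        linkage_matrix=z,
        metadata={"distance": "1 - r", "linkage": "average", "correlation": corr.method},
    )


def to_newick(dend: Dendrogram) -> str:
    """Serialize the dendrogram to Newick with branch lengths (merge-height differences)."""
    n = len(dend.labels)
    z = dend.linkage_matrix
    heights = {i: 0.0 for i in range(n)}
    for i, row in enumerate(z):
        heights[n + i] = float(row[2])

    def render(node: int, parent_height: float) -> str:
        bl = parent_height - heights[node]
        if node < n:
            return f"{dend.labels[node]}:{bl:.6g}"
        row = z[node - n]
        inner = ",".join(render(int(c), heights[node]) for c in (row[0], row[1]))
        return f"({inner}):{bl:.6g}"

    root = n + len(z) - 1
    row = z[-1]
    inner = ",".join(render(int(c), heights[root]) for c in (row[0], row[1]))
    return f"({inner});"


def first_merges_are(dend: Dendrogram, pairs: Sequence[tuple[str, str]]) -> bool:
    """True iff the first len(pairs) merges are exactly the given leaf pairs (any order)."""
    want = {tuple(sorted(p)) for p in pairs}
    got = set()
    for ma, mb, _ in dend.merges[: len(pairs)]:
        if len(ma) != 1 or len(mb) != 1:
            return False
        got.add(tuple(sorted((ma[0], mb[0]))))
    return got == want
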