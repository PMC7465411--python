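"""Comparing learned heading representations with the heading taxonomy.

The classifier's output-layer rows reflect how headings are *used* in the
notes; the taxonomy encodes how they are *intended* to be used.  Ranking all
heading pairs by model (cosine) distance and by taxonomy (shortest-path)
distance and looking at the pairs furthest apart in the two rankings
surfaces documentation-practice conflicts — typically a diagnosis heading
and an intervention heading under which nurses write identical content.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, spearmanr

from notestruct.classifier import HeadingVectorSpace
from notestruct.taxonomy import HeadingTaxonomy, tree_distance

__all__ = [
    "PairRanking",
    "cosine_pair_distances",
    "build_rankings",
    "spearman_rho",
    "conflict_pairs",
    "cluster_headings",
    "write_conflicts_tsv",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class PairRanking:
    """Fractional ranks of all unordered heading pairs under two orderings:
    ascending cosine distance (model) and ascending tree distance (taxonomy).

    Tree distances are small integers, so ties are pervasive; fractional
    (average) ranks keep the two rankings comparable.
    """

    pairs: tuple[Pair, ...]
    rank_model: np.ndarray
    rank_tree: np.ndarray

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.rank_model) or len(self.pairs) != len(self.rank_tree):
            raise ValueError("ranks must align with pairs")


def _ordered_pairs(ids: Sequence[str]) -> list[Pair]:
    ids = sorted(ids)
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


def cosine_pair_distances(vectors: HeadingVectorSpace, ids: Sequence[str]) -> dict[Pair, float]:
    """Cosine distance (1 - cosine similarity) for every unordered pair."""
    ids = sorted(set(ids))
    if len(ids) < 2:
        raise ValueError("need at least two headings")
    missing = set(ids) - set(vectors.heading_ids)
    if missing:
        raise KeyError(f"headings without vectors: {sorted(missing)[:5]}")
    return {(a, b): 1.0 - vectors.cosine(a, b) for a, b in _ordered_pairs(ids)}


def build_rankings(
    vectors: HeadingVectorSpace,
    tax: HeadingTaxonomy,
    ids: Sequence[str] | None = None,
) -> PairRanking:
    """Rank all heading pairs by model distance and by taxonomy distance.

    ``ids`` defaults to the headings present in both the vector space and
    the taxonomy (strict string match); headings unmapped on either side are
    dropped.
    """
    if ids is None:
        ids = sorted(set(vectors.heading_ids) & tax.nodes)
    else:
        ids = sorted(set(ids))
        outside = set(ids) - (set(vectors.heading_ids) & tax.nodes)
        if outside:
            raise KeyError(f"headings not in both spaces: {sorted(outside)[:5]}")
    if len(ids) < 2:
        raise ValueError("fewer than two headings map to both the model and the taxonomy")
    pairs = _ordered_pairs(ids)
    cos = cosine_pair_distances(vectors, ids)
    d_model = np.array([cos[p] for p in pairs])
    d_tree = np.array([tree_distance(tax, a, b) for a, b in pairs], dtype=float)
    return PairRanking(
        pairs=tuple(pairs),
        rank_model=rankdata(d_model, method="average"),
        rank_tree=rankdata(d_tree, method="average"),
    )


def spearman_rho(r1: Sequence[float], r2: Sequence[float]) -> float:
    """Tie-corrected Spearman correlation between two rankings."""
    r1, r2 = np.asarray(r1, dtype=float), np.asarray(r2, dtype=float)
    if r1.shape != r2.shape or r1.size < 2:
        raise ValueError("rankings must share a set of at least two pairs")
    if np.ptp(r1) == 0 or np.ptp(r2) == 0:
        raise ValueError("constant ranking has no defined correlation")
    return float(spearmanr(r1, r2).statistic)


def conflict_pairs(
    ranking: PairRanking,
    direction: str = "model_close_tree_far",
    top_n: int = 10,
) -> list[tuple[Pair, float]]:
    """Heading pairs furthest apart in the two rankings.

    ``model_close_tree_far`` sorts by ``rank_tree - rank_model`` descending:
    pairs the model finds similar (low model rank) but the taxonomy places
    far apart (high tree rank).  ``tree_close_model_far`` is the mirror
    image.  Ties break by pair identifiers.
    """
    if top_n < 0:
        raise ValueError("top_n must be >= 0")
    if direction == "model_close_tree_far":
        diff = ranking.rank_tree - ranking.rank_model
    elif direction == "tree_close_model_far":
        diff = ranking.rank_model - ranking.rank_tree
    else:
        raise ValueError(f"unknown direction {direction!r}")
    order = sorted(range(len(ranking.pairs)), key=lambda i: (-diff[i], ranking.pairs[i]))
    return [(ranking.pairs[i], float(diff[i])) for i in order[:top_n]]


def write_conflicts_tsv(
    ranking: PairRanking,
    conflicts: list[tuple[Pair, float]],
    path: str | Path,
) -> None:
    idx = {p: i for i, p in enumerate(ranking.pairs)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("heading_a\theading_b\trank_model\trank_tree\tdifference\n")
        for (a, b), diff in conflicts:
            i = idx[(a, b)]
            fh.write(f"{a}\t{b}\t{ranking.rank_model[i]:g}\t{ranking.rank_tree[i]:g}\t{diff:g}\n")


def cluster_headings(
    vectors: HeadingVectorSpace,
    ids: Sequence[str] | None = None,
    method: str = "average",
) -> str:
    """Hierarchical clustering of heading vectors under cosine distance.

    Returns the dendrogram as a Newick string whose leaf labels are the
    heading ids and whose branch lengths derive from the merge heights.
    """
    from skbio.tree import TreeNode  # deferred: heavy import

    ids = sorted(set(ids)) if ids is not None else sorted(vectors.heading_ids)
    if len(ids) < 2:
        raise ValueError("need at least two headings to cluster")
    dist = cosine_pair_distances(vectors, ids)
    condensed = np.array([dist[p] for p in _ordered_pairs(ids)])
    Z = linkage(condensed, method=method)
    tree = TreeNode.from_linkage_matrix(Z, ids)
    return str(tree).strip()
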