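"""Local Adjacency Subgroup Strategy (LASS).

Four steps:

1. min-max normalization of the mention-count matrix onto [1, 2],
2. entropy-weight method for the k index aspects
   (p -> information entropy -> information utility -> index weight),
3. TOPSIS over the weighted-normalized matrix for per-node weights
   (relative closeness to the ideal solution, normalized to sum to 1),
4. distance-1 ego subgroups around every node and the collaboration
   coverage score

       coverage_i = adj_par * sum_j weight_node_j * count(j, center_i)
                    / (amount_i - 1)

   averaging member weight x link multiplicity over the subgroup members;
   an isolated center gets the floor value 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_io import CollabNetwork, CorpusError, MentionMatrix


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_mentions(raw: pd.DataFrame, scope: str = "column") -> MentionMatrix:
    """Min-max map raw mention counts onto [1.0, 2.0].

    ``scope='column'`` (default) rescales each aspect column by its own
    extrema: data = 1 + (raw - col_min) / (col_max - col_min).  A constant
    column maps to 1.5 everywhere — the midpoint keeps the entry in range
    while carrying zero discriminating power.  ``scope='global'`` uses the
    matrix-wide extrema instead.
    """
    if raw.shape[0] < 2:
        raise CorpusError("normalization needs at least 2 agencies")
    if (raw.values < 0).any():
        raise CorpusError("raw mention counts must be non-negative")
    values = raw.to_numpy(dtype=float)
    if scope == "column":
        lo = values.min(axis=0, keepdims=True)
        hi = values.max(axis=0, keepdims=True)
    elif scope == "global":
        lo = np.full((1, values.shape[1]), values.min())
        hi = np.full((1, values.shape[1]), values.max())
    else:
        raise CorpusError(f"scope must be 'column' or 'global', got {scope!r}")
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        data = 1.0 + (values - lo) / span
    data = np.where(span == 0, 1.5, data)
    normalized = pd.DataFrame(data, index=raw.index, columns=raw.columns)
    return MentionMatrix(raw=raw, normalized=normalized)


# ---------------------------------------------------------------------------
# entropy weight method
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndexWeights:
    """Entropy-method weights for the k index aspects.

    ``p`` holds per-column proportions (each column sums to 1); utility is
    1 - entropy and weights are utilities normalized to sum to 1.
    """

    p: pd.DataFrame
    inf_entropy: pd.Series
    inf_utility: pd.Series
    weight_index: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "inf_entropy": self.inf_entropy,
                "inf_utility": self.inf_utility,
                "weight_index": self.weight_index,
            }
        ).rename_axis("aspect")


def entropy_index_weights(matrix: MentionMatrix) -> IndexWeights:
    """Entropy-weight method on the normalized mention matrix.

    p(i,j) = data(i,j) / sum_i data(i,j);
    entropy_j = -(1/ln n) sum_i p ln p;  utility_j = 1 - entropy_j;
    weight_j = utility_j / sum_j utility_j.

    The [1, 2] normalization guarantees strictly positive entries, so
    p ln p is always defined.  With all utilities zero (every column
    uniform) the weights degenerate to the uniform distribution.
    """
    data = matrix.normalized
    n = data.shape[0]
    if n < 2:
        raise CorpusError("entropy weights need at least 2 agencies (ln n normalizer)")
    values = data.to_numpy(dtype=float)
    if (values <= 0).any():
        raise CorpusError("entropy weights require strictly positive data")
    p = values / values.sum(axis=0, keepdims=True)
    entropy = -(p * np.log(p)).sum(axis=0) / math.log(n)
    utility = 1.0 - entropy
    total = utility.sum()
    if total > 0:
        weights = utility / total
    else:  # all columns uniform: no index discriminates, fall back to uniform
        weights = np.full(data.shape[1], 1.0 / data.shape[1])
    cols = data.columns
    return IndexWeights(
        p=pd.DataFrame(p, index=data.index, columns=cols),
        inf_entropy=pd.Series(entropy, index=cols),
        inf_utility=pd.Series(utility, index=cols),
        weight_index=pd.Series(weights, index=cols),
    )


# ---------------------------------------------------------------------------
# TOPSIS node weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeWeights:
    """TOPSIS results: weighted-normalized matrix, ideal-point distances,
    relative closeness, and the sum-to-one node weights."""

    z: pd.DataFrame
    z_plus: pd.Series
    z_minus: pd.Series
    dis_plus: pd.Series
    dis_minus: pd.Series
    closeness: pd.Series
    weight_node: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dis_plus": self.dis_plus,
                "dis_minus": self.dis_minus,
                "closeness": self.closeness,
                "weight_node": self.weight_node,
            }
        ).rename_axis("code")


def closeness_from_distances(dis_plus: float, dis_minus: float) -> float:
    """Relative closeness dis- / (dis- + dis+); 0.5 when both are zero."""
    total = dis_plus + dis_minus
    if total == 0:
        return 0.5
    return dis_minus / total


def topsis_node_weights(matrix: MentionMatrix, iw: IndexWeights) -> NodeWeights:
    """TOPSIS ranking of agencies over the index-weighted decision matrix.

    Z(i,j) rescales each column of data(i,j) by its raw-scale extrema and
    multiplies by the index weight; Z+ / Z- are the per-column max / min of
    Z; distances to them are Euclidean.  All indexes are benefit-type.
    Node weights are the closeness values normalized to sum to 1.
    """
    data = matrix.normalized
    values = data.to_numpy(dtype=float)
    lo = values.min(axis=0, keepdims=True)
    hi = values.max(axis=0, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (values - lo) / span
    scaled = np.where(span == 0, 0.0, scaled)
    z = scaled * iw.weight_index.to_numpy()[None, :]
    z_plus = z.max(axis=0)
    z_minus = z.min(axis=0)
    dis_plus = np.sqrt(((z - z_plus[None, :]) ** 2).sum(axis=1))
    dis_minus = np.sqrt(((z - z_minus[None, :]) ** 2).sum(axis=1))
    closeness = np.array(
        [closeness_from_distances(dp, dm) for dp, dm in zip(dis_plus, dis_minus)]
    )
    weights = normalize_closeness(pd.Series(closeness, index=data.index))
    return NodeWeights(
        z=pd.DataFrame(z, index=data.index, columns=data.columns),
        z_plus=pd.Series(z_plus, index=data.columns),
        z_minus=pd.Series(z_minus, index=data.columns),
        dis_plus=pd.Series(dis_plus, index=data.index),
        dis_minus=pd.Series(dis_minus, index=data.index),
        closeness=pd.Series(closeness, index=data.index),
        weight_node=weights,
    )


def normalize_closeness(closeness: pd.Series) -> pd.Series:
    """Node weights: closeness normalized to sum to 1."""
    total = closeness.sum()
    if total <= 0:
        raise CorpusError("cannot normalize closeness values summing to zero")
    return closeness / total


# ---------------------------------------------------------------------------
# subgroups and collaboration coverage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Subgroup:
    """Ego subgroup: a center plus every node connected to it (either
    direction), with per-member total link multiplicities."""

    center: str
    members: frozenset[str]
    member_link_count: dict[str, int]

    def __post_init__(self) -> None:
        if self.center in self.members:
            raise CorpusError(f"subgroup center {self.center!r} cannot be a member")
        if set(self.member_link_count) != set(self.members):
            raise CorpusError("member_link_count keys must equal members")
        for m, c in self.member_link_count.items():
            if c < 1:
                raise CorpusError(f"member {m!r}: link count must be >= 1, got {c}")

    @property
    def amount(self) -> int:
        """Number of nodes in the subgroup, center included."""
        return len(self.members) + 1


def build_subgroups(net: CollabNetwork) -> dict[str, Subgroup]:
    """One ego subgroup per node; membership is undirected distance-1
    adjacency and link counts sum document multiplicity in both directions."""
    subgroups = {}
    for center in net.nodes:
        members = net.neighbors(center)
        subgroups[center] = Subgroup(
            center=center,
            members=members,
            member_link_count={m: net.link_count(m, center) for m in members},
        )
    return subgroups


def collaboration_coverage(
    sub: Subgroup, node_weights: pd.Series, adj_par: float = 10.0
) -> float:
    """Collaboration coverage of a subgroup center.

    adj_par-scaled average over members j of weight_node_j * count(j,
    center).  An isolated center (amount = 1) gets the floor value 1.0.
    """
    if adj_par <= 0:
        raise CorpusError(f"adj_par must be positive, got {adj_par}")
    if sub.amount == 1:
        return 1.0
    total = sum(
        float(node_weights[m]) * sub.member_link_count[m] for m in sub.members
    )
    return adj_par * total / (sub.amount - 1)


def coverage_table(
    net: CollabNetwork, nw: NodeWeights, adj_par: float = 10.0
) -> pd.Series:
    """Collaboration coverage for every node of the network."""
    subgroups = build_subgroups(net)
    cov = pd.Series(
        {
            code: collaboration_coverage(subgroups[code], nw.weight_node, adj_par)
            for code in net.nodes
        },
        name="coverage",
    )
    cov.index.name = "code"
    return cov
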