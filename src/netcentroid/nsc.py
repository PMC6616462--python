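"""Network-adjusted nearest-shrunken-centroid engine.

The classifier follows the shrunken-centroid (PAM-style) blueprint with three
network-aware modifications:

1. the overall centroid of each edge is the *unweighted* mean of its class
   centroids, removing the bias toward large groups;
2. the standardised class statistic ``d`` of an edge is augmented with a
   neighbourhood-consistency term: the mean ``d`` of the edges sharing a node,
   scaled by a logistic factor ``psi`` in (0, 2) of the sign-agreement
   proportion among those neighbours — densely connected, consistently
   signed subnetworks are promoted over scattered signals;
3. soft-thresholding uses a group-specific threshold ``delta_k`` rescaled by
   each group's maximal adjusted statistic, so groups with smaller signal
   ranges are not shrunk away first.

Classification of a sample is by the smallest standardised squared distance
to each group's shrunken centroid minus twice the log prior; posteriors are
the softmax of minus half the discriminant scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from .io import CompositeNetwork, Edge, SampleGroups, TF
from .scoring import EdgeScoreMatrix

logger = logging.getLogger(__name__)

N_DELTA_GRID = 30

__all__ = [
    "EdgeNeighborhood",
    "CentroidModel",
    "Prediction",
    "SubnetworkSelection",
    "build_neighborhoods",
    "balanced_overall_centroid",
    "edge_statistics",
    "sign_agreement",
    "psi",
    "adjust_scores",
    "delta_grid",
    "soft_threshold",
    "fit",
]


# ---------------------------------------------------------------------------
# neighbourhoods


@dataclass
class EdgeNeighborhood:
    """Neighbour structure of the measurable network.

    ``adjacency[i, j] = 1`` iff edges i and j (i != j) share at least one
    node. ``tf_mask`` flags TF edges so neighbour sets can be partitioned by
    edge type.
    """

    edge_ids: list[str]
    adjacency: sp.csr_matrix  # boolean, symmetric, zero diagonal
    tf_mask: np.ndarray

    @property
    def sizes(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def sizes_tf(self) -> np.ndarray:
        return np.asarray(self.adjacency[:, self.tf_mask].sum(axis=1)).ravel()

    @property
    def sizes_ppi(self) -> np.ndarray:
        return np.asarray(self.adjacency[:, ~self.tf_mask].sum(axis=1)).ravel()


def build_neighborhoods(network: CompositeNetwork) -> EdgeNeighborhood:
    """Edges are neighbours when they share at least one node (gene symbol)."""
    edges = network.edges
    p = len(edges)
    nodes = sorted(network.nodes)
    node_ix = {g: i for i, g in enumerate(nodes)}
    rows, cols = [], []
    for i, e in enumerate(edges):
        for g in set(e.nodes):
            rows.append(i)
            cols.append(node_ix[g])
    incidence = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(p, len(nodes))
    )
    adj = (incidence @ incidence.T).astype(bool)
    adj.setdiag(False)
    adj.eliminate_zeros()
    tf_mask = np.array([e.etype == TF for e in edges], dtype=bool)
    return EdgeNeighborhood(network.edge_ids, adj.tocsr(), tf_mask)


# ---------------------------------------------------------------------------
# per-edge statistics


def balanced_overall_centroid(class_means: np.ndarray) -> np.ndarray:
    """Unweighted mean of the class centroids (p x K -> p)."""
    return class_means.mean(axis=1)


def edge_statistics(
    X: np.ndarray, group_idx: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    """Class centroids, balanced overall centroid, pooled SD and d statistic.

    ``X`` is edges x samples; ``group_idx`` maps each sample to 0..K-1.
    Returns (class_means, overall, s, s0, m, d) where
    ``d[i, k] = (xbar_ik - xbar_i) / (m_k * (s_i + s0))``, ``s`` is the pooled
    within-class SD (divisor n - K), ``s0`` the median of ``s`` and
    ``m_k = sqrt(1/n_k + 1/n)``.
    """
    p, n = X.shape
    if n <= K:
        raise ValueError(f"need more samples ({n}) than groups ({K})")
    counts = np.bincount(group_idx, minlength=K)
    if (counts == 0).any():
        raise ValueError("empty phenotypic group")
    class_means = np.empty((p, K))
    ss_within = np.zeros(p)
    for k in range(K):
        block = X[:, group_idx == k]
        class_means[:, k] = block.mean(axis=1)
        ss_within += ((block - class_means[:, [k]]) ** 2).sum(axis=1)
    s = np.sqrt(ss_within / (n - K))
    s0 = float(np.median(s))
    overall = balanced_overall_centroid(class_means)
    m = np.sqrt(1.0 / counts + 1.0 / n)
    denom = np.outer(s + s0, m)
    d = (class_means - overall[:, None]) / denom
    return class_means, overall, s, s0, m, d


def psi(p: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Logistic weight ``2 exp(5(p-1/2)) / (1 + exp(5(p-1/2)))`` on (0, 2).

    Maps the sign-agreement proportion ``p`` of an edge's neighbourhood to a
    multiplier: 1 at p = 0.5, approaching 2 (0) for full (no) agreement, with
    the symmetry psi(p) + psi(1-p) = 2.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("sign-agreement proportion must lie in [0, 1]")
    out = 2.0 * expit(5.0 * (arr - 0.5))
    return float(out) if np.isscalar(p) else out


def sign_agreement(d: np.ndarray, nb: EdgeNeighborhood) -> np.ndarray:
    """Proportion of neighbours whose d shares the edge's sign (sign(0)=0).

    Edges with empty neighbourhoods get NaN; the adjustment step treats them
    as carrying no neighbourhood information.
    """
    signs = np.sign(d)
    adj = nb.adjacency.astype(np.float64)
    agree = np.empty_like(d)
    n_pos = adj @ (signs == 1.0)
    n_neg = adj @ (signs == -1.0)
    n_zero = adj @ (signs == 0.0)
    agree = np.where(signs == 1.0, n_pos, np.where(signs == -1.0, n_neg, n_zero))
    sizes = nb.sizes.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = agree / sizes[:, None]
    prop[sizes == 0] = np.nan
    return prop


def adjust_scores(
    d: np.ndarray, nb: EdgeNeighborhood, form: str = "mean"
) -> np.ndarray:
    """Neighbourhood-consistency adjustment ``d* = d + psi * A``.

    ``form='mean'`` (default) uses the neighbourhood mean
    ``A = (sum_TF d + sum_PPI d) / |N|``, which keeps d* on the scale of d.
    ``form='literal'`` multiplies each type's sum by its neighbour count,
    ``A = (|N1| sum_TF d + |N2| sum_PPI d) / |N|``. Edges without neighbours
    are left unadjusted.
    """
    if form not in ("mean", "literal"):
        raise ValueError(f"unknown adjustment form {form!r}")
    adj = nb.adjacency.astype(np.float64)
    sizes = nb.sizes.astype(float)
    has_nb = sizes > 0
    if form == "mean":
        neighbor_sum = adj @ d
    else:
        adj_tf = adj[:, nb.tf_mask]
        adj_ppi = adj[:, ~nb.tf_mask]
        neighbor_sum = (
            nb.sizes_tf[:, None] * (adj_tf @ d[nb.tf_mask])
            + nb.sizes_ppi[:, None] * (adj_ppi @ d[~nb.tf_mask])
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        A = neighbor_sum / sizes[:, None]
    A[~has_nb] = 0.0
    prop = sign_agreement(d, nb)
    w = np.ones_like(d)
    w[has_nb] = psi(prop[has_nb])
    return d + w * A


def delta_grid(
    d_star: np.ndarray, form: str = "abs_dstar", d: Optional[np.ndarray] = None
) -> tuple[np.ndarray, float, np.ndarray]:
    """Shrinkage grid and group-specific scale.

    Returns ``(grid, delta_max, group_max)`` where ``group_max[k]`` is the
    group's maximal statistic, ``delta_max`` their mean over groups, and
    ``grid`` 30 equally spaced values from 0 to ``delta_max``. The default
    ``abs_dstar`` form takes ``max_i |d*_ik|``; the ``literal`` form takes the
    signed ``max_i d_ik`` of the raw statistic.
    """
    if form == "abs_dstar":
        group_max = np.abs(d_star).max(axis=0)
    elif form == "literal":
        group_max = (d_star if d is None else d).max(axis=0)
    else:
        raise ValueError(f"unknown delta form {form!r}")
    delta_max = float(group_max.mean())
    if delta_max <= 0:
        logger.warning("all adjusted statistics are zero: degenerate shrinkage grid")
        return np.array([0.0]), 0.0, group_max
    return np.linspace(0.0, delta_max, N_DELTA_GRID), delta_max, group_max


def soft_threshold(d_star: np.ndarray, delta_k: np.ndarray) -> np.ndarray:
    """``d' = sign(d*) (|d*| - delta_k)_+`` applied columnwise."""
    return np.sign(d_star) * np.maximum(0.0, np.abs(d_star) - np.asarray(delta_k))


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class Prediction:
    """Discriminant scores, hard labels and posterior probabilities."""

    scores: pd.DataFrame  # samples x groups, discriminant score delta_k
    labels: pd.Series
    posteriors: pd.DataFrame


@dataclass
class SubnetworkSelection:
    """Per-group surviving edges at a given shrinkage, with signed statistics."""

    delta: float
    per_group: dict[str, pd.DataFrame]  # columns: edge, edge_id, d, d_star, d_prime, sign

    @property
    def edge_ids(self) -> set[str]:
        out: set[str] = set()
        for df in self.per_group.values():
            out.update(df["edge_id"])
        return out


@dataclass
class CentroidModel:
    """Fitted state of the network-adjusted shrunken-centroid classifier."""

    edges: tuple[Edge, ...]
    edge_ids: list[str]
    group_labels: list[str]
    counts: np.ndarray
    class_means: np.ndarray        # p x K
    overall_centroid: np.ndarray   # p
    s: np.ndarray                  # p, pooled within-class SD
    s0: float
    m: np.ndarray                  # K
    d: np.ndarray                  # p x K
    d_star: np.ndarray             # p x K
    grid: np.ndarray
    delta_max: float
    group_max: np.ndarray          # K
    priors: np.ndarray             # K
    adjusted: bool

    @property
    def K(self) -> int:
        return len(self.group_labels)

    def delta_k(self, delta: float) -> np.ndarray:
        if delta < 0:
            raise ValueError("delta must be non-negative")
        if self.delta_max == 0:
            return np.zeros(self.K)
        return (delta / self.delta_max) * self.group_max

    def d_prime(self, delta: float) -> np.ndarray:
        return soft_threshold(self.d_star, self.delta_k(delta))

    def shrunken_centroids(self, delta: float) -> np.ndarray:
        """``xbar'_ik = xbar_i + m_k (s_i + s0) d'_ik`` (p x K)."""
        dp = self.d_prime(delta)
        return self.overall_centroid[:, None] + self.m[None, :] * (
            (self.s + self.s0)[:, None] * dp
        )

    def n_selected(self, delta: float) -> int:
        return int((np.abs(self.d_prime(delta)) > 0).any(axis=1).sum())

    def classify(
        self, scores: Union[EdgeScoreMatrix, pd.DataFrame], delta: float = 0.0
    ) -> Prediction:
        """Assign samples to the group with the smallest discriminant score.

        delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k;
        ties go to the lexicographically first group label. Posteriors are
        softmax(-delta/2) computed with max-subtraction.
        """
        data = scores.data if isinstance(scores, EdgeScoreMatrix) else scores
        if list(data.index) != self.edge_ids:
            try:
                data = data.loc[self.edge_ids]
            except KeyError as err:
                raise ValueError("edge universe mismatch between model and scores") from err
        X = data.to_numpy().T  # samples x p
        if np.isnan(X).any():
            raise ValueError("scores contain missing values; impute first")
        cent = self.shrunken_centroids(delta)  # p x K
        denom = (self.s + self.s0) ** 2
        disc = np.empty((X.shape[0], self.K))
        for k in range(self.K):
            disc[:, k] = (((X - cent[:, k]) ** 2) / denom).sum(axis=1)
        disc -= 2.0 * np.log(self.priors)[None, :]
        idx = disc.argmin(axis=1)  # argmin takes the first = lexicographic winner
        w = -0.5 * (disc - disc.min(axis=1, keepdims=True))
        post = np.exp(w)
        post /= post.sum(axis=1, keepdims=True)
        samples = data.columns
        return Prediction(
            scores=pd.DataFrame(disc, index=samples, columns=self.group_labels),
            labels=pd.Series([self.group_labels[i] for i in idx], index=samples),
            posteriors=pd.DataFrame(post, index=samples, columns=self.group_labels),
        )

    def select_subnetwork(self, delta: float) -> SubnetworkSelection:
        """Per-group edges with non-zero shrunken statistic, with sign."""
        dp = self.d_prime(delta)
        per_group: dict[str, pd.DataFrame] = {}
        for k, g in enumerate(self.group_labels):
            keep = np.abs(dp[:, k]) > 0
            per_group[g] = pd.DataFrame(
                {
                    "edge": [self.edges[i] for i in np.flatnonzero(keep)],
                    "edge_id": [self.edge_ids[i] for i in np.flatnonzero(keep)],
                    "d": self.d[keep, k],
                    "d_star": self.d_star[keep, k],
                    "d_prime": dp[keep, k],
                    "sign": np.sign(dp[keep, k]).astype(int),
                }
            )
        return SubnetworkSelection(delta=delta, per_group=per_group)


def fit(
    scores: EdgeScoreMatrix,
    groups: SampleGroups,
    *,
    adjust: bool = True,
    eq_form: str = "mean",
    delta_form: str = "abs_dstar",
    priors: str = "equal",
    neighborhoods: Optional[EdgeNeighborhood] = None,
) -> CentroidModel:
    """Fit the network-adjusted shrunken-centroid model on complete scores.

    ``adjust=False`` skips the neighbourhood term (d* = d), reducing the
    engine to a balanced-centroid NSC on interaction scores.
    """
    data = scores.data
    if data.isna().to_numpy().any():
        raise ValueError("edge scores contain missing values; run impute_missing first")
    labels = groups.labels
    assign = groups.assignments.reindex(data.columns)
    if assign.isna().any():
        missing = list(assign.index[assign.isna()])
        raise ValueError(f"samples without group assignment: {missing[:5]}")
    group_idx = np.array([labels.index(g) for g in assign])
    K = len(labels)
    X = data.to_numpy()
    class_means, overall, s, s0, m, d = edge_statistics(X, group_idx, K)
    if adjust:
        nb = neighborhoods if neighborhoods is not None else build_neighborhoods(scores.network)
        if nb.edge_ids != list(data.index):
            raise ValueError("neighborhood edge universe does not match scores")
        d_star = adjust_scores(d, nb, form=eq_form)
    else:
        d_star = d.copy()
    grid, delta_max, group_max = delta_grid(d_star, form=delta_form, d=d)
    counts = np.bincount(group_idx, minlength=K)
    if priors == "equal":
        pri = np.full(K, 1.0 / K)
    elif priors == "empirical":
        pri = counts / counts.sum()
    else:
        raise ValueError(f"unknown priors {priors!r}")
    return CentroidModel(
        edges=scores.network.edges,
        edge_ids=list(data.index),
        group_labels=labels,
        counts=counts,
        class_means=class_means,
        overall_centroid=overall,
        s=s,
        s0=s0,
        m=m,
        d=d,
        d_star=d_star,
        grid=grid,
        delta_max=delta_max,
        group_max=group_max,
        priors=pri,
        adjusted=adjust,
    )
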