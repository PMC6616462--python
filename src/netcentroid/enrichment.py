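"""Signed pathway over-representation analysis of selected subnetworks.

For each phenotypic group the selected edges are split by the sign of their
shrunken statistic (up/down relative to the overall centroid). Each direction
is tested for over-representation in pathway gene sets with the upper-tail
hypergeometric probability against the measurable universe, adjusted with
Benjamini-Hochberg per (group, direction) family. The signed significance
score is -log10(adjusted p) for up-selections and +log10(adjusted p) (a
negative magnitude) for down-selections, so heatmaps show direction by sign.

Pathway annotations describe genes, so the default sampling unit is the node:
a query is the set of genes incident to selected edges of one sign, and the
background the genes incident to any measurable edge. An edge-level mode
(an edge belongs to a pathway iff both endpoints are annotated) is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import CompositeNetwork, Edge, PathwayCollection
from .nsc import SubnetworkSelection

logger = logging.getLogger(__name__)

MIN_P_FLOOR = 1e-300

__all__ = ["split_by_sign", "hypergeom_enrich", "bh_adjust",
           "significance_scores", "enrich"]


def split_by_sign(selection: SubnetworkSelection) -> dict[tuple[str, str], set[str]]:
    """Genes incident to selected edges, per (group, direction).

    A gene touched by both an up- and a down-selected edge appears in both
    direction sets (logged).
    """
    out: dict[tuple[str, str], set[str]] = {}
    for group, df in selection.per_group.items():
        up: set[str] = set()
        down: set[str] = set()
        for row in df.itertuples(index=False):
            target = up if row.d_prime > 0 else down
            target.update(row.edge.nodes)
        both = up & down
        if both:
            logger.info("group %s: %d genes in both directions", group, len(both))
        out[(group, "up")] = up
        out[(group, "down")] = down
    return out


def hypergeom_enrich(query: set[str], pathway: set[str], background: set[str]) -> tuple[int, float]:
    """Upper-tail hypergeometric probability of the observed overlap.

    Returns (overlap, P(X >= overlap)) for X ~ Hypergeom(|background|,
    |pathway ∩ background|, |query|). The query must lie in the background;
    the pathway is intersected with it.
    """
    if not background:
        raise ValueError("empty background universe")
    if not query <= background:
        raise ValueError("query set must be a subset of the background")
    in_bg = pathway & background
    overlap = len(query & in_bg)
    p = float(hypergeom.sf(overlap - 1, len(background), len(in_bg), len(query)))
    return overlap, min(p, 1.0)


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def significance_scores(adj_p: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Signed -log10 adjusted p: positive for 'up', negative for 'down'."""
    capped = np.maximum(np.asarray(adj_p, dtype=float), MIN_P_FLOOR)
    mag = -np.log10(capped)
    sign = np.where(np.asarray(direction) == "up", 1.0, -1.0)
    return sign * mag


def _edge_in_pathway(e: Edge, members: set[str]) -> bool:
    return e.node_a in members and e.node_b in members


def enrich(
    selection: SubnetworkSelection,
    pathways: PathwayCollection,
    network: CompositeNetwork,
    *,
    unit: str = "node",
    min_pathway_size: int = 3,
) -> pd.DataFrame:
    """Enrichment table for every (group, direction, pathway) combination.

    ``network`` is the measurable network defining the background universe.
    Pathways smaller than ``min_pathway_size`` after background intersection
    are skipped.
    """
    if unit not in ("node", "edge"):
        raise ValueError(f"unknown enrichment unit {unit!r}")
    rows = []
    if unit == "node":
        background = set(network.nodes)
        queries = split_by_sign(selection)
        path_sets = {p.name: set(p.members) & background for p in pathways}
    else:
        background = {e.edge_id for e in network.edges}
        edge_of = {e.edge_id: e for e in network.edges}
        queries = {}
        for group, df in selection.per_group.items():
            queries[(group, "up")] = set(df.loc[df["d_prime"] > 0, "edge_id"])
            queries[(group, "down")] = set(df.loc[df["d_prime"] < 0, "edge_id"])
        path_sets = {
            p.name: {eid for eid, e in edge_of.items() if _edge_in_pathway(e, set(p.members))}
            for p in pathways
        }
    n_small = sum(1 for s in path_sets.values() if 0 < len(s) < min_pathway_size)
    if n_small:
        logger.info("skipping %d pathways below size %d in background", n_small, min_pathway_size)

    for (group, direction), query in sorted(queries.items()):
        if not query:
            continue
        fam = []
        for p in pathways:
            in_bg = path_sets[p.name]
            if len(in_bg) < min_pathway_size:
                continue
            overlap, pval = hypergeom_enrich(query, in_bg, background)
            fam.append(dict(
                group=group, pathway=p.name, source=p.source, direction=direction,
                overlap=overlap, query_size=len(query), pathway_size=len(in_bg),
                background_size=len(background), p_value=pval,
            ))
        if not fam:
            continue
        adj = bh_adjust([r["p_value"] for r in fam])
        scores = significance_scores(adj, np.array([direction] * len(fam)))
        for r, a, sc in zip(fam, adj, scores):
            r["adj_p"] = float(a)
            r["score"] = float(sc)
        rows.extend(fam)
    cols = ["group", "pathway", "source", "direction", "overlap", "query_size",
            "pathway_size", "background_size", "p_value", "adj_p", "score"]
    return pd.DataFrame(rows, columns=cols)
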