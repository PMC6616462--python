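"""Z-score standardisation and edge-level interaction scores.

Each omics layer (already on log2 scale) is standardised per feature across
all samples. Interaction scores then replace node-level measurements with one
value per network edge and sample:

* TF edge (protein A -> mRNA B):   e = z_prot(A) + z_mRNA(B)
* TF edge with a CNV layer:        e = z_prot(A) + (z_mRNA(B) - z_dna(B))
* PPI edge (protein A - protein B): e = z_prot(A) + z_prot(B)

Because the z's are standardised log2 values, adding/subtracting them
corresponds to multiplying/dividing the original abundances: the CNV variant
scores the TF protein against its target's transcription per DNA copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import TF, CompositeNetwork, OmicsMatrix, SampleGroups

logger = logging.getLogger(__name__)

__all__ = ["ZMatrix", "EdgeScoreMatrix", "standardize", "interaction_scores",
           "impute_missing", "write_scores"]


@dataclass
class ZMatrix:
    """Per-feature Z-scores of one omics layer (same shape and labels)."""

    omics_type: str
    data: pd.DataFrame


@dataclass
class EdgeScoreMatrix:
    """Interaction scores: measurable edges x samples.

    Row order follows ``network.edges``; a score is missing iff any
    contributing Z-score is missing.
    """

    network: CompositeNetwork
    data: pd.DataFrame

    @property
    def edges(self):
        return self.network.edges

    @property
    def samples(self) -> pd.Index:
        return self.data.columns


def standardize(layer: OmicsMatrix) -> ZMatrix:
    """Per-feature Z-scores over non-missing entries (SD with n-1 divisor).

    Features with fewer than two observed values or zero variance cannot be
    standardised and become entirely missing (with a warning).
    """
    x = layer.data
    mean = x.mean(axis=1, skipna=True)
    sd = x.std(axis=1, ddof=1, skipna=True)
    n_obs = x.notna().sum(axis=1)
    bad = (n_obs < 2) | (sd == 0) | sd.isna()
    z = x.sub(mean, axis=0).div(sd, axis=0)
    if bad.any():
        logger.warning(
            "%d features with <2 observations or zero variance set to missing",
            int(bad.sum()),
        )
        z.loc[bad] = np.nan
    return ZMatrix(layer.omics_type, z)


def interaction_scores(
    z_prot: ZMatrix,
    z_mrna: ZMatrix,
    network: CompositeNetwork,
    z_cnv: Optional[ZMatrix] = None,
) -> EdgeScoreMatrix:
    """Transform node-level Z-scores into per-edge interaction scores.

    With a CNV layer, the target-side signal is the CNV-normalised mRNA
    Z-score ``z_mRNA - z_dna``; the TF-edge formula is otherwise identical,
    and PPI edges never involve CNV.
    """
    zm = z_mrna.data
    if z_cnv is not None:
        zm = zm - z_cnv.data.reindex(index=zm.index, columns=zm.columns)
    zp = z_prot.data
    edges = network.edges
    tf_mask = np.array([e.etype == TF for e in edges], dtype=bool)
    a_genes = [e.node_a for e in edges]
    b_genes = [e.node_b for e in edges]
    ia = zp.index.get_indexer(a_genes)
    ib_tf = zm.index.get_indexer([g for g, t in zip(b_genes, tf_mask) if t])
    ib_ppi = zp.index.get_indexer([g for g, t in zip(b_genes, tf_mask) if not t])
    if (ia < 0).any() or (ib_tf < 0).any() or (ib_ppi < 0).any():
        # align_universe guarantees this never happens
        raise RuntimeError("edge references a molecule absent from the Z-matrices")
    ZP, ZM = zp.to_numpy(), zm.to_numpy()
    out = np.empty((len(edges), zp.shape[1]))
    out[tf_mask] = ZP[ia[tf_mask]] + ZM[ib_tf]
    out[~tf_mask] = ZP[ia[~tf_mask]] + ZP[ib_ppi]
    data = pd.DataFrame(
        out,
        index=pd.Index(network.edge_ids, name="edge"),
        columns=zp.columns,
    )
    return EdgeScoreMatrix(network, data)


def impute_missing(
    scores: EdgeScoreMatrix,
    strategy: str = "drop_edge",
    groups: Optional[SampleGroups] = None,
) -> EdgeScoreMatrix:
    """Produce a complete edge-score matrix.

    ``drop_edge`` removes every edge with any missing score; ``group_mean``
    fills a missing cell with the edge's mean within that sample's group,
    falling back to the edge's overall mean when the whole group is missing.
    Edges missing in all samples are dropped under either strategy.
    """
    if strategy not in ("drop_edge", "group_mean"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    data = scores.data
    all_missing = data.isna().all(axis=1)
    if all_missing.any():
        logger.warning("dropping %d edges missing in all samples", int(all_missing.sum()))
        data = data.loc[~all_missing]
    if strategy == "drop_edge":
        data = data.dropna(axis=0, how="any")
    else:
        if groups is None:
            raise ValueError("group_mean imputation requires sample groups")
        if data.isna().to_numpy().any():
            data = data.copy()
            labels = groups.assignments.reindex(data.columns)
            for g in labels.unique():
                cols = labels.index[labels == g]
                block = data[cols]
                data[cols] = block.apply(lambda r: r.fillna(r.mean()), axis=1)
            # whole-group-missing cells remain NaN: fall back to overall mean
            if data.isna().to_numpy().any():
                data = data.apply(lambda r: r.fillna(r.mean()), axis=1)
    keep_ids = set(data.index)
    net = scores.network.subset(e for e in scores.network.edges if e.edge_id in keep_ids)
    data = data.loc[net.edge_ids]
    return EdgeScoreMatrix(net, data)


def write_scores(scores: EdgeScoreMatrix, path) -> None:
    scores.data.to_csv(path, sep="\t", float_format="%.12g", na_rep="NA", index_label="edge")
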