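"""Readers, writers and alignment for omics matrices, networks, groups and pathways.

All gene and sample identifiers are treated as case-sensitive strings except
gene symbols, which are uppercased on input so that layers and networks match
on the HGNC-symbol convention regardless of file capitalisation.

File dialects
-------------
* Omics matrix: TSV, first column = feature (gene symbol), header row of
  sample identifiers, cells = log2 quantitation; ``NA`` or empty = missing.
* Network: 3-column TSV ``node_a  node_b  type`` with type ``TF`` or ``PPI``;
  for TF rows node_a is the transcription factor (protein side) and node_b
  the target gene (mRNA side). A header row is tolerated and skipped.
* Groups: 2-column TSV ``sample  group``.
* Pathways: standard GMT (name, description, member genes...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TF = "TF"
PPI = "PPI"
VALID_EDGE_TYPES = (TF, PPI)
VALID_OMICS_TYPES = ("mrna", "protein", "cnv")

__all__ = [
    "Edge",
    "OmicsMatrix",
    "CompositeNetwork",
    "SampleGroups",
    "Pathway",
    "PathwayCollection",
    "AlignedBundle",
    "read_omics_matrix",
    "write_omics_matrix",
    "read_network",
    "read_groups",
    "read_gmt",
    "align_universe",
    "write_cytoscape_files",
]


@dataclass(frozen=True)
class Edge:
    """A molecular interaction.

    For ``TF`` edges ``node_a`` is the transcription factor (quantified at the
    protein level) and ``node_b`` its target gene (quantified at the mRNA
    level, optionally per DNA copy). ``PPI`` edges pair two proteins and are
    stored with nodes in sorted order so that (A, B) and (B, A) are one edge.
    """

    node_a: str
    node_b: str
    etype: str

    @property
    def edge_id(self) -> str:
        return f"{self.node_a}:{self.node_b}:{self.etype}"

    @property
    def nodes(self) -> tuple[str, str]:
        return (self.node_a, self.node_b)


def _canonical_edge(node_a: str, node_b: str, etype: str) -> Edge:
    a, b = node_a.strip().upper(), node_b.strip().upper()
    if etype not in VALID_EDGE_TYPES:
        raise ValueError(f"unknown edge type {etype!r}; expected one of {VALID_EDGE_TYPES}")
    if etype == PPI and a > b:
        a, b = b, a
    return Edge(a, b, etype)


@dataclass
class OmicsMatrix:
    """One omics layer: features x samples, log2 scale, NaN = missing."""

    omics_type: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.omics_type not in VALID_OMICS_TYPES:
            raise ValueError(f"omics_type must be one of {VALID_OMICS_TYPES}")
        if not self.data.index.is_unique:
            raise ValueError("feature identifiers must be unique within a layer")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def subset(self, features=None, samples=None) -> "OmicsMatrix":
        data = self.data
        if features is not None:
            data = data.loc[[f for f in data.index if f in set(features)]]
        if samples is not None:
            data = data[[s for s in data.columns if s in set(samples)]]
        return OmicsMatrix(self.omics_type, data.copy())


def read_omics_matrix(path, omics_type: str) -> OmicsMatrix:
    """Read a TSV omics table (features x samples, log2 values).

    Duplicate feature rows are collapsed by their mean (with a warning);
    ``NA``/empty cells become missing. A non-numeric cell raises a parse
    error naming the offending row and column.
    """
    raw = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=True,
        na_values=["", "NA", "NaN", "nan"],
    )
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"{path}: empty omics table")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at feature "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    values.index = values.index.astype(str).str.strip().str.upper()
    values.columns = values.columns.astype(str).str.strip()
    if not values.index.is_unique:
        n_dup = values.index.size - values.index.nunique()
        logger.warning(
            "%s: %d duplicated feature rows collapsed by mean", path, n_dup
        )
        # groupby(sort=False) keeps first-seen feature order
        values = values.groupby(level=0, sort=False).mean()
    return OmicsMatrix(omics_type, values)


def write_omics_matrix(layer: OmicsMatrix, path) -> None:
    layer.data.to_csv(path, sep="\t", float_format="%.12g", na_rep="NA", index_label="feature")


@dataclass
class CompositeNetwork:
    """Union of TF-regulatory and protein-protein interaction edges.

    The graph is undirected for neighbourhood purposes; TF edges retain the
    TF/target role annotation because interaction scoring needs to know which
    side is protein and which is mRNA.
    """

    edges: tuple[Edge, ...]

    @classmethod
    def from_edges(cls, rows: Iterable[tuple[str, str, str]]) -> "CompositeNetwork":
        seen: dict[Edge, None] = {}
        n_self = 0
        for a, b, t in rows:
            e = _canonical_edge(a, b, t)
            if e.etype == PPI and e.node_a == e.node_b:
                n_self += 1
                continue
            seen.setdefault(e, None)
        if n_self:
            logger.warning("dropped %d self-loop PPI edges", n_self)
        return cls(tuple(seen))

    @property
    def edge_ids(self) -> list[str]:
        return [e.edge_id for e in self.edges]

    @property
    def tf_edges(self) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.etype == TF)

    @property
    def ppi_edges(self) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.etype == PPI)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.update(e.nodes)
        return out

    def subset(self, edges: Iterable[Edge]) -> "CompositeNetwork":
        keep = set(edges)
        return CompositeNetwork(tuple(e for e in self.edges if e in keep))

    def __len__(self) -> int:
        return len(self.edges)


def read_network(path) -> CompositeNetwork:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     names=["node_a", "node_b", "type"])
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty network file")
    rows = []
    for i, (a, b, t) in enumerate(df.itertuples(index=False)):
        t_norm = str(t).strip().upper()
        if i == 0 and t_norm not in VALID_EDGE_TYPES and t_norm in ("TYPE", "EDGE_TYPE", "INTERACTION"):
            continue  # header row
        if t_norm not in VALID_EDGE_TYPES:
            raise ValueError(f"{path} line {i + 1}: unknown edge type {t!r}")
        rows.append((str(a), str(b), t_norm))
    return CompositeNetwork.from_edges(rows)


@dataclass
class SampleGroups:
    """Sample -> phenotypic-group assignment.

    Requires at least two groups with at least two samples each, the minimum
    for pooled within-class variances.
    """

    assignments: pd.Series

    def __post_init__(self) -> None:
        s = self.assignments.astype(str)
        if not s.index.is_unique:
            raise ValueError("duplicate sample identifiers in group assignments")
        self.assignments = s
        counts = s.value_counts()
        if len(counts) < 2:
            raise ValueError("need at least two phenotypic groups")
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"groups with fewer than 2 samples: {sorted(small.index)}"
            )

    @property
    def samples(self) -> pd.Index:
        return self.assignments.index

    @property
    def labels(self) -> list[str]:
        return sorted(self.assignments.unique())

    @property
    def K(self) -> int:
        return len(self.labels)

    @property
    def counts(self) -> pd.Series:
        return self.assignments.value_counts().reindex(self.labels)

    def subset(self, samples: Sequence[str]) -> "SampleGroups":
        keep = [s for s in self.assignments.index if s in set(samples)]
        missing_groups = set(self.assignments.unique()) - set(self.assignments.loc[keep].unique())
        sub = self.assignments.loc[keep]
        bad = sorted(missing_groups | set(sub.value_counts()[lambda c: c < 2].index))
        if bad:
            raise ValueError(f"fewer than 2 surviving samples in groups: {bad}")
        return SampleGroups(sub)


def read_groups(path) -> SampleGroups:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     names=["sample", "group"])
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty group file")
    s = pd.Series(df["group"].values, index=df["sample"].values)
    return SampleGroups(s)


@dataclass(frozen=True)
class Pathway:
    name: str
    source: str
    members: tuple[str, ...]


@dataclass
class PathwayCollection:
    pathways: tuple[Pathway, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.pathways]
        if len(names) != len(set(names)):
            raise ValueError("pathway names must be unique")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)


def read_gmt(path) -> PathwayCollection:
    """Read a GMT gene-set file; member symbols are uppercased and
    deduplicated, lines with fewer than three fields are skipped."""
    pathways: dict[str, Pathway] = {}
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            fields = [f.strip() for f in line.rstrip("\n").split("\t") if f.strip()]
            if len(fields) < 3:
                if line.strip():
                    n_skipped += 1
                continue
            name, source = fields[0], fields[1]
            members = tuple(dict.fromkeys(g.upper() for g in fields[2:]))
            if name in pathways:
                logger.warning("duplicate pathway name %r: keeping first", name)
                continue
            pathways[name] = Pathway(name, source, members)
    if n_skipped:
        logger.warning("%s: skipped %d malformed GMT lines", path, n_skipped)
    return PathwayCollection(tuple(pathways.values()))


@dataclass
class AlignedBundle:
    """Layers, network and groups restricted to a common measurable universe."""

    mrna: OmicsMatrix
    protein: OmicsMatrix
    network: CompositeNetwork
    groups: SampleGroups
    cnv: Optional[OmicsMatrix] = None


def _measured(layer: OmicsMatrix, samples: Sequence[str]) -> set[str]:
    sub = layer.data[list(samples)]
    return set(sub.index[sub.notna().any(axis=1)])


def align_universe(
    mrna: OmicsMatrix,
    protein: OmicsMatrix,
    network: CompositeNetwork,
    groups: SampleGroups,
    cnv: Optional[OmicsMatrix] = None,
) -> AlignedBundle:
    """Restrict samples, features and edges to a consistent universe.

    Samples are the intersection of all provided layers and the group table.
    An edge is *measurable* when every molecule it needs has a (not entirely
    missing) feature row: protein(node_a) and mRNA(node_b) for TF edges (plus
    CNV(node_b) when a copy-number layer is given), protein(node_a) and
    protein(node_b) for PPI edges. Molecules off every surviving edge are
    dropped, so a second application is a no-op.
    """
    layers = [mrna, protein] + ([cnv] if cnv is not None else [])
    common = [s for s in mrna.samples if all(s in l.samples for l in layers)
              and s in set(groups.samples)]
    if len(common) < 2:
        raise ValueError("fewer than 2 samples shared by all layers and the group table")
    groups_aligned = groups.subset(common)

    prot_meas = _measured(protein, common)
    mrna_meas = _measured(mrna, common)
    cnv_meas = _measured(cnv, common) if cnv is not None else None

    kept = []
    for e in network.edges:
        if e.etype == TF:
            ok = e.node_a in prot_meas and e.node_b in mrna_meas
            if ok and cnv_meas is not None:
                ok = e.node_b in cnv_meas
        else:
            ok = e.node_a in prot_meas and e.node_b in prot_meas
        if ok:
            kept.append(e)
    if not kept:
        raise ValueError("no measurable edges: network and omics layers do not overlap")
    net = network.subset(kept)

    need_prot: set[str] = set()
    need_mrna: set[str] = set()
    for e in net.edges:
        if e.etype == TF:
            need_prot.add(e.node_a)
            need_mrna.add(e.node_b)
        else:
            need_prot.update(e.nodes)

    logger.info(
        "aligned universe: %d samples, %d measurable edges (%d TF, %d PPI)",
        len(common), len(net), len(net.tf_edges), len(net.ppi_edges),
    )
    return AlignedBundle(
        mrna=mrna.subset(features=need_mrna, samples=common),
        protein=protein.subset(features=need_prot, samples=common),
        network=net,
        groups=groups_aligned,
        cnv=cnv.subset(features=need_mrna, samples=common) if cnv is not None else None,
    )


def write_cytoscape_files(selection, out_dir) -> tuple[Path, Path]:
    """Export node/edge attribute tables loadable in Cytoscape.

    ``selection`` is a :class:`netcentroid.nsc.SubnetworkSelection`. The edge
    table carries the group, the sign of the shrunken statistic and its value;
    the node table tags each gene with its molecule type (TF targets are the
    mRNA side, everything else protein) and the groups where it was selected.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edge_rows = []
    node_info: dict[tuple[str, str], set[str]] = {}
    for group, df in selection.per_group.items():
        for row in df.itertuples(index=False):
            e: Edge = row.edge
            edge_rows.append(
                dict(node_a=e.node_a, node_b=e.node_b, type=e.etype, group=group,
                     sign="up" if row.d_prime > 0 else "down", d_prime=row.d_prime)
            )
            if e.etype == TF:
                node_info.setdefault((e.node_a, "protein"), set()).add(group)
                node_info.setdefault((e.node_b, "mRNA"), set()).add(group)
            else:
                node_info.setdefault((e.node_a, "protein"), set()).add(group)
                node_info.setdefault((e.node_b, "protein"), set()).add(group)
    edge_path = out_dir / "cytoscape_edges.tsv"
    node_path = out_dir / "cytoscape_nodes.tsv"
    pd.DataFrame(edge_rows, columns=["node_a", "node_b", "type", "group", "sign", "d_prime"]).to_csv(
        edge_path, sep="\t", index=False, float_format="%.6g")
    node_rows = [
        dict(gene=g, molecule_type=mt, groups=";".join(sorted(grps)))
        for (g, mt), grps in sorted(node_info.items())
    ]
    pd.DataFrame(node_rows, columns=["gene", "molecule_type", "groups"]).to_csv(
        node_path, sep="\t", index=False)
    return edge_path, node_path
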