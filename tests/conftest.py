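import numpy as np
import pandas as pd
import pytest

from netcentroid import CompositeNetwork, OmicsMatrix, SampleGroups
from netcentroid.scoring import EdgeScoreMatrix


def chain_network(n_edges, etype="PPI"):
    """Path graph N0-N1-...: each interior edge has two neighbours."""
    return CompositeNetwork.from_edges(
        [(f"N{i}", f"N{i + 1}", etype) for i in range(n_edges)]
    )


def disjoint_network(n_edges, etype="PPI"):
    """n_edges PPI edges with no shared nodes: empty neighbourhoods."""
    return CompositeNetwork.from_edges(
        [(f"A{i}", f"B{i}", etype) for i in range(n_edges)]
    )


def make_groups(sizes, labels=None):
    labels = labels or [f"G{k + 1}" for k in range(len(sizes))]
    assign, names = [], []
    c = 0
    for lab, size in zip(labels, sizes):
        for _ in range(size):
            c += 1
            names.append(f"S{c}")
            assign.append(lab)
    return SampleGroups(pd.Series(assign, index=names))


def make_scores(network, groups, seed=0, shift=None):
    """Random complete edge-score matrix; ``shift`` maps edge index ->
    per-group mean offsets (tuple of length K)."""
    rng = np.random.default_rng(seed)
    n = len(groups.samples)
    p = len(network)
    X = rng.normal(size=(p, n))
    if shift:
        labels = groups.labels
        assign = groups.assignments.to_numpy()
        for i, offsets in shift.items():
            for k, lab in enumerate(labels):
                X[i, assign == lab] += offsets[k]
    data = pd.DataFrame(X, index=network.edge_ids, columns=groups.samples)
    return EdgeScoreMatrix(network, data)


@pytest.fixture
def two_groups():
    return make_groups([6, 6], ["A", "B"])


@pytest.fixture
def toy_study(tmp_path):
    """A small on-disk study: 2 TF + 3 PPI edges, 12 samples, 2 groups.

    Edge TF1->G1 and PPI P1-P2 carry a planted group difference.
    """
    rng = np.random.default_rng(42)
    genes_prot = ["TF1", "P1", "P2", "P3"]
    genes_mrna = ["G1", "G2"]
    samples = [f"S{i + 1}" for i in range(12)]
    groups = ["A"] * 6 + ["B"] * 6
    prot = pd.DataFrame(rng.normal(size=(4, 12)), index=genes_prot, columns=samples)
    mrna = pd.DataFrame(rng.normal(size=(2, 12)), index=genes_mrna, columns=samples)
    prot.loc["TF1", prot.columns[:6]] += 2.5
    prot.loc["P1", prot.columns[:6]] += 2.0
    prot.loc["P2", prot.columns[:6]] += 2.0
    mrna.loc["G1", mrna.columns[:6]] += 2.5
    edges = [
        ("TF1", "G1", "TF"),
        ("TF1", "G2", "TF"),
        ("P1", "P2", "PPI"),
        ("P2", "P3", "PPI"),
        ("TF1", "P1", "PPI"),
    ]
    d = tmp_path / "study"
    d.mkdir()
    prot.to_csv(d / "protein.tsv", sep="\t", index_label="feature")
    mrna.to_csv(d / "mrna.tsv", sep="\t", index_label="feature")
    with open(d / "network.tsv", "w") as fh:
        for a, b, t in edges:
            fh.write(f"{a}\t{b}\t{t}\n")
    with open(d / "groups.tsv", "w") as fh:
        for s, g in zip(samples, groups):
            fh.write(f"{s}\t{g}\n")
    with open(d / "pathways.gmt", "w") as fh:
        fh.write("PW_SIGNAL\tsrc\tTF1\tG1\tP1\tP2\n")
        fh.write("PW_OTHER\tsrc\tP3\tG2\tTF1\n")
    return d
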