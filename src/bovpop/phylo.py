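"""Breed-origin phylogeny: mean genotypes, IBS distance, Neighbor-Joining.

Population relationships are summarized by per-population mean genotype
vectors; the identity-by-state distance between populations j and k is
``mean_m |mean_j(m) - mean_k(m)| / 2``, bounded in [0, 1] (0 for
identical mean genotypes, 1 for fixation on opposite alleles at every
marker).  The unrooted tree is built by canonical Saitou-Nei
Neighbor-Joining, which recovers additive (tree-metric) distances
exactly; negative branch lengths are clamped to zero with the deficit
moved to the sibling edge.  Trees are scikit-bio ``TreeNode`` objects
and serialize to standard Newick.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode

from bovpop.genotype_io import MISSING, GenotypeDataset

__all__ = [
    "population_mean_genotypes",
    "ibs_distance_matrix",
    "neighbor_joining",
    "write_newick",
    "read_newick",
]


def population_mean_genotypes(ds: GenotypeDataset) -> pd.DataFrame:
    """Mean non-missing dosage per population per marker.

    Markers with zero non-missing calls in any population are dropped
    from all populations (their ids are listed in ``result.attrs``).
    """
    groups = ds.samples.groupby("population", observed=True).indices
    means = {}
    counts = {}
    for pop, idx in groups.items():
        sub = ds.calls[np.sort(idx), :]
        obs = sub != MISSING
        n = obs.sum(axis=0)
        s = np.where(obs, sub, 0).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            means[pop] = np.where(n > 0, s / n, np.nan)
        counts[pop] = n
    table = pd.DataFrame(means, index=ds.markers["marker_id"]).T
    bad = table.columns[table.isna().any(axis=0)]
    if len(bad):
        table = table.drop(columns=bad)
    table.attrs["dropped_markers"] = list(bad)
    return table


def ibs_distance_matrix(means: pd.DataFrame) -> pd.DataFrame:
    """Normalized mean allele-sharing mismatch between population means.

    ``d(j, k) = mean_m |mean_j - mean_k| / 2``; symmetric with zero
    diagonal, bounded in [0, 1].
    """
    if means.isna().any().any():
        raise ValueError("means matrix must be complete")
    labels = list(means.index)
    M = means.to_numpy(dtype=np.float64)
    d = np.abs(M[:, None, :] - M[None, :, :]).mean(axis=2) / 2.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=labels, columns=labels)


def neighbor_joining(d: pd.DataFrame) -> TreeNode:
    """Saitou-Nei Neighbor-Joining tree from a distance matrix.

    Ties in the Q criterion break on the smallest index pair so runs are
    deterministic; negative branch lengths are clamped to zero and the
    deficit added to the sibling edge.  The returned tree is unrooted
    (trifurcating root) and exact on additive inputs.
    """
    D = np.asarray(d, dtype=np.float64)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    labels = list(d.index)
    n = len(labels)
    if n < 3:
        raise ValueError("Neighbor-Joining needs at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=str(x)) for x in labels]
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        a, b = np.unravel_index(np.argmin(Q), Q.shape)  # first minimum = smallest index pair
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = dij / 2.0 + (r[a] - r[b]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0.0:
            lj += -li  # move deficit to the sibling edge
            li = 0.0
        if lj < 0.0:
            li += -lj
            lj = 0.0
        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.extend([nodes[i], nodes[j]])
        new_d = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, active] = new_d
        D[active, -1] = new_d
        D[-1, -1] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    i, j, m = active
    # three-point formulas for the final star join
    li = (D[i, j] + D[i, m] - D[j, m]) / 2.0
    lj = (D[i, j] + D[j, m] - D[i, m]) / 2.0
    lm = (D[i, m] + D[j, m] - D[i, j]) / 2.0
    root = TreeNode()
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[m], lm)):
        node.length = float(max(length, 0.0))
        root.append(node)
    return root


def write_newick(tree: TreeNode, path) -> None:
    """Serialize a tree to a Newick file with branch lengths."""
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
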