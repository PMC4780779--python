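"""Independent brute-force oracles used by the tests.

Everything here recomputes quantities from first principles (path walks,
pairwise MRCA searches, dynamic programming), deliberately avoiding the
package's own covariance/transformation code paths.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np


def root_to_leaf_path(tree: dendropy.Tree, label: str) -> list[dendropy.Node]:
    leaf = [l for l in tree.leaf_node_iter() if l.taxon.label == label][0]
    path = []
    node = leaf
    while node is not None:
        path.append(node)
        node = node.parent_node
    return list(reversed(path))  # root ... leaf


def brute_force_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """V[i,j] = summed branch lengths on the shared prefix of the two root paths."""
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    paths = {l: root_to_leaf_path(tree, l) for l in labels}
    n = len(labels)
    V = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            pa, pb = paths[a], paths[b]
            shared = 0.0
            for x, y in zip(pa[1:], pb[1:]):  # skip the root itself
                if x is not y:
                    break
                shared += x.edge.length
            V[i, j] = shared
    return labels, V


def stem_length_of_mrca(tree: dendropy.Tree, members: list[str]) -> float:
    """Branch length subtending the MRCA of ``members``, by comparing root paths."""
    paths = [root_to_leaf_path(tree, m) for m in members]
    depth = 0
    while all(len(p) > depth for p in paths) and all(
        p[depth] is paths[0][depth] for p in paths
    ):
        depth += 1
    mrca = paths[0][depth - 1]
    return mrca.edge.length if mrca.edge.length is not None else 0.0


def grafen_vcv_via_tree_rebuild(tree: dendropy.Tree, rho: float) -> tuple[list[str], np.ndarray]:
    """Grafen structure by actually building the height-transformed tree.

    Node height = (descendant tips − 1)/(n − 1), tips at 0; transformed
    h' = h**rho; a new tree with branch lengths h'(parent) − h'(child) then
    yields the covariance as plain root-to-MRCA path sums.
    """
    clone = dendropy.Tree.get(
        data=tree.as_string(schema="newick"), schema="newick",
        preserve_underscores=True, suppress_internal_node_taxa=True,
    )
    n = len(clone.leaf_nodes())
    heights = {}
    for node in clone.postorder_node_iter():
        k = len(list(node.leaf_iter()))
        heights[node] = ((k - 1) / (n - 1)) ** rho if k > 1 else 0.0
    heights[clone.seed_node] = 1.0  # root spans the full unit height
    for node in clone.preorder_node_iter():
        if node is not clone.seed_node:
            node.edge.length = heights[node.parent_node] - heights[node]
    return brute_force_vcv(clone)


def acdc_vcv_bruteforce(tree: dendropy.Tree, g: float) -> tuple[list[str], np.ndarray]:
    """ACDC covariance from transformed node depths and pairwise MRCA search."""
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    depth = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[node.parent_node] + node.edge.length
    T = max(depth[l] for l in tree.leaf_node_iter())

    def transformed(d: float) -> float:
        if abs(g - 1.0) < 1e-12:
            return d
        return (T / math.log(g)) * (g ** (d / T) - 1.0)

    paths = {l: root_to_leaf_path(tree, l) for l in labels}
    n = len(labels)
    V = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            pa, pb = paths[a], paths[b]
            mrca = pa[0]
            for x, y in zip(pa, pb):
                if x is not y:
                    break
                mrca = x
            V[i, j] = transformed(depth[mrca])
    return labels, V


def sankoff_parsimony_score(tree: dendropy.Tree, states: dict[str, str]) -> int:
    """Minimal state changes on the tree (unit costs; exact for polytomies)."""
    alphabet = sorted(set(states.values()))
    INF = 10**9
    cost: dict[dendropy.Node, dict[str, int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states[node.taxon.label]
            cost[node] = {a: (0 if a == s else INF) for a in alphabet}
        else:
            cost[node] = {
                a: sum(
                    min(cost[c][b] + (0 if a == b else 1) for b in alphabet)
                    for c in node.child_nodes()
                )
                for a in alphabet
            }
    return min(cost[tree.seed_node].values())


def direct_mvn_loglik(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Multivariate-normal log density via slogdet + solve (no Cholesky reuse)."""
    n = len(y)
    diff = y - mean
    _, logdet = np.linalg.slogdet(cov)
    return float(
        -0.5 * (n * math.log(2 * math.pi) + logdet + diff @ np.linalg.solve(cov, diff))
    )
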