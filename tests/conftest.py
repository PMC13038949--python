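"""Shared fixtures: small hand-built trees and brute-force oracles."""

import itertools

import numpy as np
import pytest

from ecophylo.mk import MkModel, mk_transition_matrix
from ecophylo.trees import Phylogeny, parse_newick


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_tree():
    return parse_newick("((A:1,B:1):0.5,(C:0.7,D:0.7):0.8);")


def two_taxon_tree(t: float) -> Phylogeny:
    """Cherry with total tip-to-tip divergence ``t``."""
    return Phylogeny(parent=np.array([2, 2, -1]),
                     children=[[], [], [0, 1]],
                     edge_length=np.array([t / 2, t / 2, 0.0]),
                     tip_labels=["A", "B"])


# ------------------------------------------------- brute-force Mk oracles

def brute_force_mk_loglik(tree: Phylogeny, states, model: MkModel) -> float:
    """Sum the joint likelihood over every internal-state assignment."""
    k = model.k
    internals = list(range(tree.n_tips, tree.n_nodes))
    P = {n: mk_transition_matrix(model, float(tree.edge_length[n]))
         for n in range(tree.n_nodes)}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        for i in range(tree.n_tips):
            amap[i] = int(states[i])
        lik = 1.0 / k
        for n in range(tree.n_nodes):
            p = tree.parent[n]
            if p >= 0:
                lik *= P[n][amap[p], amap[n]]
        total += lik
    return float(np.log(total)) if total > 0 else -np.inf


def brute_force_mk_marginal(tree: Phylogeny, states, model: MkModel,
                            node: int) -> np.ndarray:
    """Posterior state distribution at one node by exhaustive enumeration."""
    k = model.k
    internals = list(range(tree.n_tips, tree.n_nodes))
    P = {n: mk_transition_matrix(model, float(tree.edge_length[n]))
         for n in range(tree.n_nodes)}
    w = np.zeros(k)
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        for i in range(tree.n_tips):
            amap[i] = int(states[i])
        lik = 1.0 / k
        for n in range(tree.n_nodes):
            p = tree.parent[n]
            if p >= 0:
                lik *= P[n][amap[p], amap[n]]
        w[amap[node]] += lik
    return w / w.sum()


def random_tree(rng: np.random.Generator, n_tips: int) -> Phylogeny:
    """Random ultrametric tree via the package-independent coalescent scheme."""
    # repeatedly join two random active lineages at increasing heights
    active = list(range(n_tips))
    heights = {i: 0.0 for i in active}
    parent = {}
    lengths = {}
    children = {i: [] for i in active}
    h = 0.0
    next_id = n_tips
    while len(active) > 1:
        h += float(rng.exponential(1.0))
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        children[next_id] = [a, b]
        heights[next_id] = h
        for c in (a, b):
            parent[c] = next_id
            lengths[c] = h - heights[c]
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    n_nodes = next_id
    parr = np.full(n_nodes, -1, dtype=np.intp)
    larr = np.zeros(n_nodes)
    ch = [children.get(i, []) for i in range(n_nodes)]
    for c, p in parent.items():
        parr[c] = p
        larr[c] = lengths[c]
    return Phylogeny(parent=parr, children=ch, edge_length=larr,
                     tip_labels=[f"t{i}" for i in range(n_tips)])
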