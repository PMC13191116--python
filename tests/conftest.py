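"""Shared fixtures and independent oracles for the test suite.

The brute-force likelihood oracle enumerates internal-node state
assignments and exponentiates rate matrices directly through scipy,
deliberately sharing no code path with the pruning engine.
"""
from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from phylomix.alignment import Alignment
from phylomix.distance import DistanceMatrix
from phylomix.submodels import MixtureModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def brute_force_lnl(tree, aln: Alignment, mixture: MixtureModel) -> float:
    """Site likelihood by explicit summation over internal states."""
    comps = mixture.components()
    states = range(aln.alphabet.size)
    internals = [n for n in tree.postorder() if not n.is_leaf]
    total = 0.0
    for site in range(aln.n_sites):
        chars = {t: aln.data[aln.taxa.index(t), site] for t in aln.taxa}
        L = 0.0
        for (_c, model, r, w) in comps:
            P = {n.uid: expm(model.Q * n.length * r)
                 for n in tree.postorder() if n.parent is not None}
            tot = 0.0
            for assign in itertools.product(states, repeat=len(internals)):
                amap = {n.uid: s for n, s in zip(internals, assign)}
                p = model.root_freqs[amap[tree.root.uid]]
                for n in tree.postorder():
                    if n.parent is None:
                        continue
                    ps = amap[n.parent.uid]
                    if n.is_leaf:
                        row = aln.alphabet.partial_row(chars[n.label])
                        p *= float((P[n.uid][ps] * row).sum())
                    else:
                        p *= P[n.uid][ps, amap[n.uid]]
                tot += p
            L += w * tot
        total += np.log(L)
    return total


def path_distance_matrix(tree) -> DistanceMatrix:
    """Additive (patristic) distances by ancestor-chain walks."""
    leaves = tree.leaves()
    chains = {}
    for leaf in leaves:
        node, acc, chain = leaf, 0.0, {}
        while node is not None:
            chain[node.uid] = acc
            acc += node.length
            node = node.parent
        chains[leaf.label] = chain
    names = [l.label for l in leaves]
    D = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            best = min(chains[a][u] + chains[b][u]
                       for u in chains[a] if u in chains[b])
            D[i, j] = D[j, i] = best
    return DistanceMatrix(names, D)


def random_alignment(rng, taxa, n_sites, alphabet_chars="ACGT") -> Alignment:
    data = rng.choice(list(alphabet_chars), size=(len(taxa), n_sites))
    return Alignment(list(taxa), data)
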