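"""Pairwise ML distances and Neighbor-Joining starting trees."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment
from .submodels import MixtureModel, SubstitutionModel, jc
from .trees import Node, Tree

__all__ = ["DistanceMatrix", "ml_pairwise_distances", "jc_distance", "nj_tree"]

MAX_DISTANCE = 10.0


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair):
        a, b = pair
        return self.values[self.taxa.index(a), self.taxa.index(b)]


def jc_distance(p_hat: float, n_states: int = 4) -> float:
    """Closed-form ML distance from the mismatch proportion."""
    c = (n_states - 1) / n_states
    if p_hat >= c:
        return MAX_DISTANCE
    return float(-c * np.log(1.0 - p_hat / c))


def _pair_counts(aln: Alignment, i: int, j: int) -> np.ndarray:
    """Joint unambiguous state counts for one sequence pair."""
    s = aln.alphabet.size
    states = list(aln.alphabet.states)
    a = aln.data[i]
    b = aln.data[j]
    ok = np.isin(a, states) & np.isin(b, states)
    lut = {ch: k for k, ch in enumerate(states)}
    ai = np.array([lut[ch] for ch in a[ok]], dtype=np.int64)
    bi = np.array([lut[ch] for ch in b[ok]], dtype=np.int64)
    C = np.zeros((s, s))
    np.add.at(C, (ai, bi), 1.0)
    return C


def ml_pairwise_distances(aln: Alignment,
                          model: SubstitutionModel | MixtureModel | None = None,
                          ) -> DistanceMatrix:
    """Distance maximizing the two-sequence likelihood for every pair.

    Saturated pairs (no information at any finite distance) are capped
    at ``MAX_DISTANCE`` with a warning.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least two taxa")
    if model is None:
        model = jc(aln.alphabet) if aln.alphabet.size == 4 else jc(aln.alphabet)
    if isinstance(model, MixtureModel):
        if model.n_classes != 1:
            raise ValueError("pairwise distances use a single-class model")
        model = model.classes[0][0]
    pi = model.freqs
    n_states = aln.alphabet.size
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            C = _pair_counts(aln, i, j)
            total = C.sum()
            if total == 0:
                D[i, j] = D[j, i] = MAX_DISTANCE
                continue
            off = model.Q[~np.eye(n_states, dtype=bool)]
            if np.allclose(off, off[0]) and np.allclose(pi, 1.0 / n_states):
                # equal-rates model: the ML distance has a closed form
                p_hat = (total - np.trace(C)) / total
                d = jc_distance(float(p_hat), n_states)
                if d >= MAX_DISTANCE:
                    warnings.warn(
                        f"saturated pair ({aln.taxa[i]}, {aln.taxa[j]}); "
                        f"distance capped at {MAX_DISTANCE}")
                D[i, j] = D[j, i] = min(d, MAX_DISTANCE)
                continue

            def neg(t: float) -> float:
                P = model.transition_probabilities(t)
                with np.errstate(divide="ignore"):
                    lg = np.log(np.maximum(pi[:, None] * P, 1e-300))
                return -float((C * lg).sum())

            res = minimize_scalar(neg, bounds=(1e-8, MAX_DISTANCE),
                                  method="bounded", options={"xatol": 1e-10})
            d = float(res.x)
            if d > MAX_DISTANCE * 0.999:
                warnings.warn(f"saturated pair ({aln.taxa[i]}, {aln.taxa[j]}); "
                              f"distance capped at {MAX_DISTANCE}")
                d = MAX_DISTANCE
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(aln.taxa), D)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei Neighbor-Joining with the standard Q-criterion.

    Ties in the Q-criterion are broken by the lexicographically lowest
    (i, j) index pair of the current node list; negative estimated
    branch lengths are clamped to zero. Returns an unrooted tree
    (trifurcating pseudo-root).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("Neighbor-Joining needs at least 3 taxa")
    nodes: list[Node] = [Node(t) for t in dm.taxa]
    D = dm.values.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        u = Node()
        a, b = nodes[i], nodes[j]
        a.length = max(li, 0.0)
        b.length = max(lj, 0.0)
        u.add(a)
        u.add(b)
        duk = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = duk[keep]
        D = newD
        nodes = [nodes[k] for k in keep] + [u]

    root = Node()
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [0.5 * (d01 + d02 - d12), 0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01)]
    for node, L in zip(nodes, lens):
        node.length = max(L, 0.0)
        root.add(node)
    return Tree(root, rooted=False)
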