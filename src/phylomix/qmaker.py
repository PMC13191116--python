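"""Joint ML estimation of a shared substitution matrix from a set of
alignments.

Block-coordinate ascent: (1) with the shared matrix fixed, each
alignment's branch lengths (and, for nonreversible estimation, its root
position) are refitted; (2) with trees fixed, the shared exchangeability
(or full off-diagonal rate) parameters maximize the summed
log-likelihood by bounded quasi-Newton. The loop repeats until the total
log-likelihood gain falls below tolerance.

Exchangeabilities are optimized on the log scale with the last entry
fixed at one, which removes the scale redundancy; the returned matrix is
mean-rate-one normalized at its frequencies. Reversible estimates use
frequencies pooled from empirical counts across alignments.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .alignment import Alignment, compress_patterns
from .distance import ml_pairwise_distances, nj_tree
from .likelihood import log_likelihood, optimize_branch_lengths
from .rooting import best_rooting
from .submodels import (MixtureModel, SubstitutionModel,
                        write_paml_matrix)
from .trees import Tree

__all__ = ["MatrixEstimate", "estimate_matrix", "estimate_nonreversible"]

_LOGB = (np.log(1e-3), np.log(1e3))


@dataclass
class MatrixEstimate:
    model: SubstitutionModel
    exchangeabilities: np.ndarray | None     # flat upper-triangle order
    rates: np.ndarray | None                 # flat off-diagonal (nonreversible)
    freqs: np.ndarray
    trees: list[Tree]
    lnl: float
    trace: list = field(default_factory=list)
    converged: bool = True
    low_information: bool = False

    def write(self, path) -> None:
        write_paml_matrix(self.model, path)


def _pooled_freqs(alignments: list[Alignment]) -> np.ndarray:
    s = alignments[0].alphabet.size
    counts = np.zeros(s)
    for aln in alignments:
        counts += aln.empirical_frequencies() * aln.n_sites * aln.n_taxa
    return counts / counts.sum()


def _check_inputs(alignments, trees):
    if not alignments:
        raise ValueError("need at least one alignment")
    alphabet = alignments[0].alphabet
    for aln in alignments[1:]:
        if aln.alphabet.name != alphabet.name:
            raise ValueError("alignments use different alphabets")
    if trees is not None and len(trees) != len(alignments):
        raise ValueError("one tree per alignment required")
    return alphabet


def _initial_trees(alignments, trees):
    out = []
    for i, aln in enumerate(alignments):
        if trees is not None:
            t, _ = trees[i].copy()
            t.unroot()
        else:
            t = nj_tree(ml_pairwise_distances(aln))
        out.append(t)
    return out


def _tri_indices(s: int):
    return [(i, j) for i in range(s) for j in range(i + 1, s)]


def _build_reversible(x: np.ndarray, alphabet, freqs) -> SubstitutionModel:
    s = alphabet.size
    R = np.zeros((s, s))
    vals = np.concatenate([np.exp(x), [1.0]])
    for (i, j), v in zip(_tri_indices(s), vals):
        R[i, j] = R[j, i] = v
    return SubstitutionModel(alphabet, "Qest", exchangeabilities=R, freqs=freqs)


def _build_nonreversible(x: np.ndarray, alphabet) -> SubstitutionModel:
    s = alphabet.size
    Q = np.zeros((s, s))
    vals = np.concatenate([np.exp(x), [1.0]])
    Q[~np.eye(s, dtype=bool)] = vals
    return SubstitutionModel(alphabet, "NQest", rate_matrix=Q)


def estimate_matrix(alignments: list[Alignment], trees: list[Tree] | None = None,
                    *, tol: float = 0.1, max_outer: int = 30,
                    init_rates: np.ndarray | None = None,
                    low_info_sites: int = 200) -> MatrixEstimate:
    """Estimate shared reversible exchangeabilities from alignments.

    Trees default to Neighbor-Joining topologies; frequencies are pooled
    empirical counts. A total input below ``low_info_sites`` sites flags
    the result low-information.
    """
    alphabet = _check_inputs(alignments, trees)
    freqs = _pooled_freqs(alignments)
    pals = [compress_patterns(a) for a in alignments]
    work = _initial_trees(alignments, trees)

    s = alphabet.size
    n_free = s * (s - 1) // 2 - 1
    if init_rates is None:
        x = np.zeros(n_free)
    else:
        r = np.asarray(init_rates, float)
        if r.shape[0] == n_free + 1:
            r = r[:n_free] / r[-1]
        x = np.log(r)

    def total(xv, trees_now) -> float:
        model = MixtureModel.single(_build_reversible(xv, alphabet, freqs))
        return sum(log_likelihood(t, p, model)
                   for t, p in zip(trees_now, pals))

    lnl = total(x, work)
    trace = [lnl]
    converged = False
    for _outer in range(max_outer):
        model = MixtureModel.single(_build_reversible(x, alphabet, freqs))
        work = [optimize_branch_lengths(t, p, model, tol=1e-3, max_sweeps=3)[0]
                for t, p in zip(work, pals)]

        res = minimize(lambda xv: -total(xv, work), x, method="L-BFGS-B",
                       bounds=[_LOGB] * n_free,
                       options={"maxiter": 50, "ftol": 1e-10})
        if -res.fun > total(x, work):
            x = res.x
        new_lnl = total(x, work)
        trace.append(new_lnl)
        if new_lnl - lnl < tol:
            lnl = max(lnl, new_lnl)
            converged = True
            break
        lnl = new_lnl

    model = _build_reversible(x, alphabet, freqs)
    ex = np.array([model.exchangeabilities[i, j] for i, j in _tri_indices(s)])
    low = sum(a.n_sites for a in alignments) < low_info_sites
    return MatrixEstimate(model, ex, None, freqs, work, lnl, trace,
                          converged, low)


def estimate_nonreversible(alignments: list[Alignment],
                           trees: list[Tree] | None = None, *,
                           tol: float = 0.1, max_outer: int = 30,
                           optimize_roots: bool = True) -> MatrixEstimate:
    """Estimate a shared fully nonreversible rate matrix.

    Per-alignment trees are treated as rooted: in each outer round the
    root position of every alignment's topology is re-optimized over its
    branches under the current matrix.
    """
    alphabet = _check_inputs(alignments, trees)
    pals = [compress_patterns(a) for a in alignments]
    work = _initial_trees(alignments, trees)

    s = alphabet.size
    n_free = s * (s - 1) - 1
    x = np.zeros(n_free)

    def total(xv, trees_now) -> float:
        model = MixtureModel.single(_build_nonreversible(xv, alphabet))
        return sum(log_likelihood(t, p, model)
                   for t, p in zip(trees_now, pals))

    lnl = total(x, work)
    trace = [lnl]
    converged = False
    for _outer in range(max_outer):
        model = MixtureModel.single(_build_nonreversible(x, alphabet))
        new_work = []
        for t, p in zip(work, pals):
            t2, _ = optimize_branch_lengths(t, p, model, tol=1e-3, max_sweeps=3)
            if optimize_roots:
                t2 = best_rooting(t2, p, model, optimize_split=True).tree
            new_work.append(t2)
        # re-rooting moves the pseudo-root; keep only if it helped overall
        if total(x, new_work) >= total(x, work):
            work = new_work

        res = minimize(lambda xv: -total(xv, work), x, method="L-BFGS-B",
                       bounds=[_LOGB] * n_free,
                       options={"maxiter": 50, "ftol": 1e-10})
        if -res.fun > total(x, work):
            x = res.x
        new_lnl = total(x, work)
        trace.append(new_lnl)
        if new_lnl - lnl < tol:
            lnl = max(lnl, new_lnl)
            converged = True
            break
        lnl = new_lnl

    model = _build_nonreversible(x, alphabet)
    rates = model.Q[~np.eye(s, dtype=bool)].copy()
    rates = rates / rates[-1] if rates[-1] > 0 else rates
    low = sum(a.n_sites for a in alignments) < 200
    return MatrixEstimate(model, None, rates, model.freqs, work, lnl, trace,
                          converged, low)
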