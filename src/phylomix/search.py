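"""Hill-climbing topology search by nearest-neighbor interchange.

Desk-scale search: every internal branch contributes its two NNI
rearrangements per round; candidates are scored with the central branch
re-optimized, the best branch-disjoint set of improving moves is
applied, branch lengths are re-swept and the gain re-verified. The trace
of accepted log-likelihoods is non-decreasing by construction.
"""
from __future__ import annotations

from .alignment import Alignment, PatternAlignment, compress_patterns
from .fitting import optimize_model
from .likelihood import FitResult, optimize_branch_lengths
from .modelspec import parse_model_string
from .trees import Tree

__all__ = ["nni_search"]


def _apply_nni(tree: Tree, edge_child, which: int) -> None:
    """In-place NNI: swap child ``which`` of the edge's child node with
    the first sibling of the child node."""
    v = edge_child
    u = v.parent
    sibs = [c for c in u.children if c is not v]
    c = sibs[0]
    a = v.children[which]
    v.children[v.children.index(a)] = c
    u.children[u.children.index(c)] = a
    a.parent, c.parent = u, v


def nni_search(start: Tree, data, modelspec, *, max_rounds: int = 20,
               tol: float = 1e-4, refit_model: bool = True,
               ) -> tuple[Tree, FitResult]:
    """Local search over NNI moves from a starting tree.

    The model is fitted once on the start tree, held fixed while moves
    are scored, and refitted on the final topology. Returns the local
    optimum and its fit.
    """
    if isinstance(modelspec, str):
        modelspec = parse_model_string(modelspec)
    pal = data if isinstance(data, PatternAlignment) else compress_patterns(data)
    work, _ = start.copy()
    work.unroot()

    fit = optimize_model(work, pal, modelspec, tol=max(tol, 1e-3))
    mixture = fit.mixture
    work = fit.tree
    current = fit.lnl
    trace = [current]

    for _round in range(max_rounds):
        moves = []  # (gain, split_key, which, new_lnl)
        clades = work.clades()
        all_leaves = frozenset(work.leaf_names())
        for uid in work.nni_edges():
            for which, cand in enumerate(work.nni_neighbors(uid)):
                cand_edges = {e.uid for e in cand.edges() if not e.is_leaf}
                opt, lnl = optimize_branch_lengths(
                    cand, pal, mixture, tol=tol, max_sweeps=1,
                    edge_uids=cand_edges)
                if lnl > current + tol:
                    side = clades[uid]
                    key = frozenset([side, all_leaves - side])
                    moves.append((lnl - current, key, uid, which))
        if not moves:
            break
        moves.sort(key=lambda m: -m[0])

        # apply the best branch-disjoint subset, then re-verify
        backup = work.to_newick()
        used_nodes: set[int] = set()
        edge_by_uid = {e.uid: e for e in work.edges()}
        applied = 0
        for gain, key, uid, which in moves:
            v = edge_by_uid.get(uid)
            if v is None or v.parent is None:
                continue
            touched = {v.uid, v.parent.uid, *(c.uid for c in v.children),
                       *(c.uid for c in v.parent.children)}
            if touched & used_nodes:
                continue
            _apply_nni(work, v, which)
            used_nodes |= touched
            applied += 1
        work, lnl = optimize_branch_lengths(work, pal, mixture, tol=tol,
                                            max_sweeps=3)
        if lnl < current - 1e-9:
            # simultaneous moves interfered; fall back to the single best
            from .trees import parse_newick
            work = parse_newick(backup)
            gain, key, uid, which = moves[0]
            edge_by_uid = {e.uid: e for e in work.edges()}
            # uid belongs to the pre-backup tree; relocate by split
            clades2 = work.clades()
            target = None
            for e in work.edges():
                if e.is_leaf:
                    continue
                side = clades2[e.uid]
                if frozenset([side, all_leaves - side]) == key:
                    target = e
                    break
            if target is None:
                break
            _apply_nni(work, target, which)
            work, lnl = optimize_branch_lengths(work, pal, mixture, tol=tol,
                                                max_sweeps=3)
            if lnl <= current:
                break
        current = lnl
        trace.append(current)

    if refit_model:
        fit = optimize_model(work, pal, modelspec, tol=max(tol, 1e-3))
        work = fit.tree
    fit.extras["nni_trace"] = trace
    fit.extras["accepted_rounds"] = len(trace) - 1
    return work, fit
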