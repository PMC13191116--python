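"""Root placement under nonreversible models and rootstrap support.

A nonreversible substitution process breaks the pulley principle: the
likelihood depends on where the root sits on the (fixed) unrooted
topology, so the root can be inferred without an outgroup. Rootstrap
support for a branch is the fraction of nonparametric bootstrap
replicates whose maximum-likelihood root lies on that branch.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment, PatternAlignment, compress_patterns
from .fitting import optimize_model
from .likelihood import edge_name, log_likelihood, optimize_branch_lengths
from .modelspec import ModelSpec, parse_model_string
from .submodels import MixtureModel
from .trees import Tree

__all__ = ["RootPlacement", "RootstrapResult", "best_rooting", "rootstrap"]


@dataclass
class RootPlacement:
    edge_name: str
    lnl: float
    tree: Tree              # rooted at the winning branch
    per_edge_lnl: dict


@dataclass
class RootstrapResult:
    supports: dict          # edge name -> support in [0, 1]
    B: int
    edge_order: list

    def top_edge(self) -> str:
        return max(self.edge_order,
                   key=lambda e: (self.supports[e], -self.edge_order.index(e)))


def _canonical_edges(tree: Tree) -> list[tuple[int, str]]:
    clades = tree.clades()
    pairs = [(e.uid, edge_name(e, clades)) for e in tree.edges()]
    pairs.sort(key=lambda p: p[1])
    return pairs


def best_rooting(tree: Tree, data, mixture: MixtureModel,
                 optimize_split: bool = True) -> RootPlacement:
    """Evaluate every rooting of a fixed unrooted topology.

    For each branch the root splits the branch length; the split point
    is optimized in one dimension (total length held fixed). Ties are
    broken by the lowest branch in canonical (name-sorted) edge order.
    """
    pal = data if isinstance(data, PatternAlignment) else compress_patterns(data)
    work, uid_map = tree.copy()
    work.unroot()
    per_edge = {}
    best = None
    for uid, name in _canonical_edges(work):
        edge = next(e for e in work.edges() if e.uid == uid)
        L = edge.length

        def lnl_at(frac: float) -> float:
            rooted = work.reroot_on_edge(uid, frac * L)
            return log_likelihood(rooted, pal, mixture)

        if optimize_split and L > 1e-9:
            res = minimize_scalar(lambda f: -lnl_at(f), bounds=(0.0, 1.0),
                                  method="bounded", options={"xatol": 0.02})
            frac, lnl = float(res.x), -float(res.fun)
            mid = lnl_at(0.5)
            if mid > lnl:
                frac, lnl = 0.5, mid
        else:
            frac, lnl = 0.5, lnl_at(0.5)
        per_edge[name] = lnl
        if best is None or lnl > best[0] + 1e-12:
            best = (lnl, name, uid, frac)
    lnl, name, uid, frac = best
    edge = next(e for e in work.edges() if e.uid == uid)
    rooted = work.reroot_on_edge(uid, frac * edge.length)
    return RootPlacement(name, lnl, rooted, per_edge)


def rootstrap(aln: Alignment, tree: Tree, modelspec, B: int = 100,
              seed: int = 0, refit: str = "none",
              tol: float = 1e-3) -> RootstrapResult:
    """Bootstrap support for the root position on a fixed topology.

    Requires a nonreversible model (a reversible one cannot identify the
    root). The model is fitted once on the full data; each of the B
    site-bootstrap replicates then places the root at the branch
    maximizing the likelihood over all rootings. With ``refit="brlen"``
    branch lengths are re-optimized per replicate before root placement.
    """
    if isinstance(modelspec, str):
        modelspec = parse_model_string(modelspec)
    if isinstance(modelspec, ModelSpec):
        if not modelspec.nonreversible:
            raise ValueError("rootstrap requires a nonreversible model; "
                             "a reversible model cannot identify the root")
    elif isinstance(modelspec, MixtureModel):
        if all(m.reversible for m, _ in modelspec.classes):
            raise ValueError("rootstrap requires a nonreversible model; "
                             "a reversible model cannot identify the root")
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")

    work, _ = tree.copy()
    work.unroot()

    if isinstance(modelspec, MixtureModel):
        mixture = modelspec
        fit_tree, _ = optimize_branch_lengths(work, aln, mixture, tol=tol)
    else:
        fit = optimize_model(work, aln, modelspec, tol=tol)
        mixture = fit.mixture
        fit_tree = fit.tree
        fit_tree.unroot()

    edge_names = [name for _uid, name in _canonical_edges(fit_tree)]
    counts = {name: 0 for name in edge_names}
    rng = np.random.default_rng(seed)
    for _b in range(B):
        rep = aln.bootstrap(rng)
        rep_pal = compress_patterns(rep)
        if refit == "brlen":
            rep_tree, _ = optimize_branch_lengths(fit_tree, rep_pal, mixture,
                                                  tol=tol, max_sweeps=2)
        else:
            rep_tree = fit_tree
        placement = best_rooting(rep_tree, rep_pal, mixture,
                                 optimize_split=(refit == "brlen"))
        counts[placement.edge_name] += 1
    supports = {name: counts[name] / B for name in edge_names}
    return RootstrapResult(supports, B, edge_names)
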