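"""Pruning-algorithm likelihoods for (mixture) substitution models.

The engine computes per-pattern log-likelihoods by Felsenstein pruning
with per-node rescaling (so 200+ taxon alignments stay finite), exposes
conditional likelihoods per mixture class (the EM workhorse), optimizes
branch lengths one edge at a time via the up/down decomposition
L_i(t) = sum_ab U_i(a) P_ab(t) D_i(b), and differentiates the likelihood
with respect to branch lengths analytically (dP/dt = QP on one edge).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import Alignment, PatternAlignment, compress_patterns
from .submodels import MixtureModel, SubstitutionModel
from .trees import Node, Tree

__all__ = ["SiteLikelihoods", "FitResult", "BranchCurvature",
           "site_log_likelihoods", "log_likelihood",
           "optimize_branch_lengths", "branch_gradient_hessian",
           "export_dating_file", "read_dating_file", "edge_name"]

BRANCH_MIN, BRANCH_MAX = 1e-6, 10.0


def _as_patterns(data) -> PatternAlignment:
    if isinstance(data, PatternAlignment):
        return data
    if isinstance(data, Alignment):
        return compress_patterns(data)
    raise TypeError("expected Alignment or PatternAlignment")


def _check_taxa(tree: Tree, pal: PatternAlignment) -> None:
    tree_taxa = set(tree.leaf_names())
    aln_taxa = set(pal.taxa)
    missing = aln_taxa - tree_taxa
    if missing:
        raise ValueError(f"taxon not in tree: {sorted(missing)[0]!r}")
    extra = tree_taxa - aln_taxa
    if extra:
        raise ValueError(f"tree leaf not in alignment: {sorted(extra)[0]!r}")


def _leaf_partials(pal: PatternAlignment) -> dict[str, np.ndarray]:
    cache = getattr(pal, "_leaf_partial_cache", None)
    if cache is not None:
        return cache
    out = {}
    for row, taxon in enumerate(pal.taxa):
        col = pal.patterns[:, row]
        uniq, inv = np.unique(col, return_inverse=True)
        rows = np.stack([pal.alphabet.partial_row(u) for u in uniq])
        out[taxon] = rows[inv]
    pal._leaf_partial_cache = out
    return out


def edge_name(node: Node, clades: dict[int, frozenset]) -> str:
    """Stable edge identifier: leaf label, or sorted clade membership."""
    if node.is_leaf:
        return node.label
    return "|".join(sorted(clades[node.uid]))


class _CompTables:
    """Down/up conditional-likelihood tables for one mixture component
    (one substitution model at one rate multiplier)."""

    __slots__ = ("model", "rate", "down", "dscale", "up", "uscale",
                 "P", "pattern_lnl", "root_uid")

    def __init__(self, tree: Tree, leaf_parts: dict[str, np.ndarray],
                 model: SubstitutionModel, rate: float, need_up: bool = False):
        self.model = model
        self.rate = rate
        n_pat = next(iter(leaf_parts.values())).shape[0]
        s = model.alphabet.size
        down: dict[int, np.ndarray] = {}
        dscale: dict[int, np.ndarray] = {}
        P: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.parent is not None:
                P[node.uid] = model.transition_probabilities(node.length * rate)
            if node.is_leaf:
                down[node.uid] = leaf_parts[node.label]
                dscale[node.uid] = np.zeros(n_pat)
            else:
                D = np.ones((n_pat, s))
                sc = np.zeros(n_pat)
                for c in node.children:
                    D *= down[c.uid] @ P[c.uid].T
                    sc += dscale[c.uid]
                mx = D.max(axis=1)
                nz = mx > 0
                D[nz] /= mx[nz, None]
                with np.errstate(divide="ignore"):
                    sc = sc + np.log(mx)
                down[node.uid], dscale[node.uid] = D, sc
        self.down, self.dscale, self.P = down, dscale, P
        self.root_uid = tree.root.uid
        rootL = down[tree.root.uid] @ model.root_freqs
        with np.errstate(divide="ignore"):
            self.pattern_lnl = np.log(rootL) + dscale[tree.root.uid]
        self.up = self.uscale = None
        if need_up:
            self._build_up(tree, n_pat, s)

    def _build_up(self, tree: Tree, n_pat: int, s: int):
        up: dict[int, np.ndarray] = {}
        uscale: dict[int, np.ndarray] = {}
        pi = self.model.root_freqs
        for node in tree.preorder():
            for child in node.children:
                if node.parent is None:
                    U = np.tile(pi, (n_pat, 1))
                    sc = np.zeros(n_pat)
                else:
                    U = up[node.uid] @ self.P[node.uid]
                    sc = uscale[node.uid].copy()
                for sib in node.children:
                    if sib is child:
                        continue
                    U = U * (self.down[sib.uid] @ self.P[sib.uid].T)
                    sc += self.dscale[sib.uid]
                mx = U.max(axis=1)
                nz = mx > 0
                U[nz] /= mx[nz, None]
                with np.errstate(divide="ignore"):
                    sc = sc + np.log(mx)
                up[child.uid], uscale[child.uid] = U, sc
        self.up, self.uscale = up, uscale

    def edge_loglik(self, uid: int, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-pattern (log A, scale) through one edge with transition
        matrix P substituted on it; total log-lik = log A + scale."""
        A = ((self.up[uid] @ P) * self.down[uid]).sum(axis=1)
        return A, self.uscale[uid] + self.dscale[uid]


@dataclass
class SiteLikelihoods:
    """Per-pattern log-likelihoods and the mixture decomposition."""

    pattern_lnl: np.ndarray        # (n_pat,)
    class_lnl: np.ndarray          # (k, n_pat), conditional on class
    class_weights: np.ndarray      # (k,)
    weights: np.ndarray            # pattern multiplicities
    site_to_pattern: np.ndarray

    @property
    def total(self) -> float:
        return float(self.weights @ self.pattern_lnl)

    def site_lnl(self) -> np.ndarray:
        return self.pattern_lnl[self.site_to_pattern]

    def class_posteriors(self) -> np.ndarray:
        """(n_pat, k) posterior class membership per pattern."""
        with np.errstate(divide="ignore"):
            logw = np.log(self.class_weights)[:, None]
        lp = logw + self.class_lnl
        lp -= logsumexp(lp, axis=0, keepdims=True)
        return np.exp(lp).T


def site_log_likelihoods(tree: Tree, data, mixture: MixtureModel) -> SiteLikelihoods:
    pal = _as_patterns(data)
    _check_taxa(tree, pal)
    leaf_parts = _leaf_partials(pal)
    comps = mixture.components()
    k = mixture.n_classes
    n_pat = pal.n_patterns
    # log conditional likelihood per component, then combine
    comp_lnl = np.empty((len(comps), n_pat))
    for idx, (c, model, r, w) in enumerate(comps):
        tab = _CompTables(tree, leaf_parts, model, r)
        comp_lnl[idx] = tab.pattern_lnl
    class_lnl = np.full((k, n_pat), -np.inf)
    for c in range(k):
        rows = [i for i, (ci, *_rest) in enumerate(comps) if ci == c]
        catw = np.array([comps[i][3] for i in rows])
        # conditional on the class: category weights renormalized
        catw = catw / catw.sum() if catw.sum() > 0 else np.full(len(rows), 1.0 / len(rows))
        with np.errstate(divide="ignore"):
            class_lnl[c] = logsumexp(comp_lnl[rows] + np.log(catw)[:, None], axis=0)
    with np.errstate(divide="ignore"):
        logom = np.log(mixture.weights)[:, None]
    pattern_lnl = logsumexp(class_lnl + logom, axis=0)
    return SiteLikelihoods(pattern_lnl, class_lnl, mixture.weights.copy(),
                           pal.weights, pal.site_to_pattern)


def log_likelihood(tree: Tree, data, mixture: MixtureModel) -> float:
    if isinstance(mixture, SubstitutionModel):
        mixture = MixtureModel.single(mixture)
    return site_log_likelihoods(tree, data, mixture).total


# ---------------------------------------------------------------------------
# branch-length optimization
# ---------------------------------------------------------------------------

def _component_list(mixture: MixtureModel):
    return mixture.components()


def _all_tables(tree, leaf_parts, comps, need_up):
    return [_CompTables(tree, leaf_parts, m, r, need_up=need_up)
            for (_c, m, r, _w) in comps]


def optimize_branch_lengths(tree: Tree, data, mixture: MixtureModel,
                            tol: float = 1e-4, max_sweeps: int = 50,
                            bounds: tuple[float, float] = (BRANCH_MIN, BRANCH_MAX),
                            edge_uids=None) -> tuple[Tree, float]:
    """Coordinate-wise ML branch lengths on a fixed topology.

    Each edge is optimized by bounded 1-D search on the up/down
    decomposition; sweeps repeat until the log-likelihood gain over a
    full sweep drops below ``tol``. Returns a new tree.
    """
    if isinstance(mixture, SubstitutionModel):
        mixture = MixtureModel.single(mixture)
    pal = _as_patterns(data)
    _check_taxa(tree, pal)
    work, uid_map = tree.copy()
    if edge_uids is not None:
        edge_uids = {uid_map[u].uid for u in edge_uids}
    leaf_parts = _leaf_partials(pal)
    comps = _component_list(mixture)
    logw = np.array([np.log(w) if w > 0 else -np.inf for *_, w in comps])

    def total_lnl() -> float:
        tabs = _all_tables(work, leaf_parts, comps, need_up=False)
        L = np.stack([t.pattern_lnl for t in tabs]) + logw[:, None]
        return float(pal.weights @ logsumexp(L, axis=0))

    last = total_lnl()
    if not np.isfinite(last):
        raise ValueError("non-finite log-likelihood at start: data/model mismatch?")
    for _sweep in range(max_sweeps):
        for edge in work.edges():
            if edge_uids is not None and edge.uid not in edge_uids:
                continue
            tabs = _all_tables(work, leaf_parts, comps, need_up=True)

            def neg(t: float) -> float:
                terms = np.empty((len(comps), pal.n_patterns))
                for i, ((_c, model, r, _w), tab) in enumerate(zip(comps, tabs)):
                    P = model.transition_probabilities(t * r)
                    A, sc = tab.edge_loglik(edge.uid, P)
                    with np.errstate(divide="ignore"):
                        terms[i] = np.log(np.maximum(A, 1e-300)) + sc + logw[i]
                return -float(pal.weights @ logsumexp(terms, axis=0))

            res = minimize_scalar(neg, bounds=bounds, method="bounded",
                                  options={"xatol": 1e-10})
            if -res.fun > -neg(edge.length):
                edge.length = float(res.x)
        cur = total_lnl()
        if cur - last < tol:
            last = max(cur, last)
            break
        last = cur
    return work, last


# ---------------------------------------------------------------------------
# curvature (gradient / Hessian of branch lengths)
# ---------------------------------------------------------------------------

@dataclass
class BranchCurvature:
    edge_names: list[str]
    lengths: np.ndarray
    gradient: np.ndarray
    hessian: np.ndarray


def _gradient(tree: Tree, pal: PatternAlignment, mixture: MixtureModel,
              edge_uids: list[int]) -> np.ndarray:
    """Analytic d lnL / d t for each listed edge."""
    leaf_parts = _leaf_partials(pal)
    comps = _component_list(mixture)
    logw = np.array([np.log(w) if w > 0 else -np.inf for *_, w in comps])
    tabs = _all_tables(tree, leaf_parts, comps, need_up=True)
    comp_lnl = np.stack([t.pattern_lnl for t in tabs]) + logw[:, None]
    pat_lnl = logsumexp(comp_lnl, axis=0)
    post = np.exp(comp_lnl - pat_lnl[None, :])  # component posterior per pattern
    edge_by_uid = {e.uid: e for e in tree.edges()}
    g = np.zeros(len(edge_uids))
    for b, uid in enumerate(edge_uids):
        t = edge_by_uid[uid].length
        acc = np.zeros(pal.n_patterns)
        for i, ((_c, model, r, _w), tab) in enumerate(zip(comps, tabs)):
            P = tab.P[uid]
            dP = r * (model.Q @ P)
            A = ((tab.up[uid] @ P) * tab.down[uid]).sum(axis=1)
            B = ((tab.up[uid] @ dP) * tab.down[uid]).sum(axis=1)
            ratio = np.where(A > 0, B / np.maximum(A, 1e-300), 0.0)
            acc += post[i] * ratio
        g[b] = float(pal.weights @ acc)
    return g


def branch_gradient_hessian(tree: Tree, data, mixture: MixtureModel,
                            method: str = "analytic",
                            fd_step: float = 1e-5) -> BranchCurvature:
    """Gradient vector and Hessian matrix of lnL in the branch lengths.

    ``analytic``: exact gradient via dP/dt = QP on each edge; Hessian by
    central differences of the analytic gradient. ``central-diff``: both
    by finite differences of lnL.
    """
    if isinstance(mixture, SubstitutionModel):
        mixture = MixtureModel.single(mixture)
    pal = _as_patterns(data)
    _check_taxa(tree, pal)
    work, _ = tree.copy()
    edges = work.edges()
    for e in edges:
        if e.length <= 0:
            warnings.warn(f"zero-length branch; evaluating at {BRANCH_MIN}")
            e.length = BRANCH_MIN
    clades = work.clades()
    names = [edge_name(e, clades) for e in edges]
    uids = [e.uid for e in edges]
    lengths = np.array([e.length for e in edges])
    n = len(edges)
    mix = mixture

    def lnl_at(vec: np.ndarray) -> float:
        for e, t in zip(edges, vec):
            e.length = float(t)
        return log_likelihood(work, pal, mix)

    def grad_at(vec: np.ndarray) -> np.ndarray:
        for e, t in zip(edges, vec):
            e.length = float(t)
        return _gradient(work, pal, mix, uids)

    if method == "analytic":
        g = grad_at(lengths)
        H = np.zeros((n, n))
        for b in range(n):
            h = fd_step * max(1.0, abs(lengths[b]))
            lo = max(lengths[b] - h, BRANCH_MIN / 10)
            hi = lengths[b] + h
            vp, vm = lengths.copy(), lengths.copy()
            vp[b], vm[b] = hi, lo
            H[:, b] = (grad_at(vp) - grad_at(vm)) / (hi - lo)
    elif method == "central-diff":
        g = np.zeros(n)
        for b in range(n):
            h = fd_step * max(1.0, abs(lengths[b]))
            vp, vm = lengths.copy(), lengths.copy()
            vp[b] += h
            vm[b] = max(vm[b] - h, BRANCH_MIN / 10)
            g[b] = (lnl_at(vp) - lnl_at(vm)) / (vp[b] - vm[b])
        H = np.zeros((n, n))
        base = lnl_at(lengths)
        for a in range(n):
            for b in range(a, n):
                h = fd_step * 10
                vpp, vpm, vmp, vmm = (lengths.copy() for _ in range(4))
                vpp[[a, b]] += h
                vpm[a] += h
                vpm[b] -= h
                vmp[a] -= h
                vmp[b] += h
                vmm[[a, b]] -= h
                if a == b:
                    H[a, a] = (lnl_at(lengths + _unit(n, a, h)) - 2 * base
                               + lnl_at(lengths - _unit(n, a, h))) / h ** 2
                else:
                    H[a, b] = H[b, a] = (lnl_at(vpp) - lnl_at(vpm)
                                         - lnl_at(vmp) + lnl_at(vmm)) / (4 * h * h)
    else:
        raise ValueError(f"unknown method {method!r}")
    lnl_at(lengths)  # restore
    H = 0.5 * (H + H.T)
    return BranchCurvature(names, lengths, g, H)


def _unit(n: int, i: int, h: float) -> np.ndarray:
    v = np.zeros(n)
    v[i] = h
    return v


# ---------------------------------------------------------------------------
# dating export (gradient/Hessian hand-off file)
# ---------------------------------------------------------------------------

_FMT = "%.17g"


def export_dating_file(curvature: BranchCurvature, tree: Tree, path) -> None:
    """Write the fixed topology plus branch lengths, gradient and Hessian
    in a plain-text layout (see docs/methods.md) for approximate-likelihood
    divergence-time samplers."""
    n = len(curvature.edge_names)
    if not (curvature.gradient.shape == (n,) and curvature.hessian.shape == (n, n)
            and curvature.lengths.shape == (n,)):
        raise ValueError("curvature dimensions disagree with edge list")
    lines = [str(tree.n_leaves), tree.to_newick(precision=10)]
    lines.append("branch-lengths " + " ".join(_FMT % x for x in curvature.lengths))
    lines.append("gradient " + " ".join(_FMT % x for x in curvature.gradient))
    lines.append(f"hessian {n}")
    for row in curvature.hessian:
        lines.append(" ".join(_FMT % x for x in row))
    from pathlib import Path as _P
    _P(path).write_text("\n".join(lines) + "\n")


def read_dating_file(path) -> tuple[int, str, BranchCurvature]:
    from pathlib import Path as _P
    lines = _P(path).read_text().splitlines()
    n_taxa = int(lines[0])
    newick = lines[1]
    lengths = np.array([float(x) for x in lines[2].split()[1:]])
    gradient = np.array([float(x) for x in lines[3].split()[1:]])
    n = int(lines[4].split()[1])
    H = np.array([[float(x) for x in lines[5 + i].split()] for i in range(n)])
    return n_taxa, newick, BranchCurvature([""] * n, lengths, gradient, H)


# ---------------------------------------------------------------------------
# fit result container
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    lnl: float
    mixture: MixtureModel
    tree: Tree
    n_free_params: int
    sites: SiteLikelihoods
    trace: list = field(default_factory=list)
    converged: bool = True
    model_string: str | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return int(self.sites.site_to_pattern.shape[0])
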