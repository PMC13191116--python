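"""Mixtures across sites and trees (MAST).

The site likelihood is a weighted sum over a user-provided set of
topologies, L_i = sum_t lambda_t L_i(T_t), with tree weights lambda on
the probability simplex, per-tree branch lengths, and a substitution
model either shared (linked) or per-tree (unlinked). Fitting is EM:
the E-step computes per-site tree posteriors; the M-step re-estimates
lambda in closed form and improves branch lengths (and model
parameters) on posterior-weighted data, so the log-likelihood trace is
non-decreasing. The special case of identical topologies with unlinked
branch lengths is a branch-length mixture (the GHOST idea).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .alignment import Alignment, PatternAlignment, compress_patterns
from .fitting import MixtureTemplate, optimize_model
from .likelihood import optimize_branch_lengths, site_log_likelihoods
from .modelspec import parse_model_string
from .submodels import MixtureModel
from .trees import Tree

__all__ = ["MastFit", "fit_mast", "site_assignments"]


@dataclass
class MastFit:
    trees: list[Tree]
    tree_weights: np.ndarray
    models: list[MixtureModel]
    lnl: float
    pattern_posteriors: np.ndarray      # (n_pat, m)
    site_to_pattern: np.ndarray
    trace: list = field(default_factory=list)
    converged: bool = True
    unidentifiable_groups: list = field(default_factory=list)
    n_free_params: int = 0

    @property
    def m(self) -> int:
        return len(self.trees)


def _weighted_pal(pal: PatternAlignment, w: np.ndarray) -> PatternAlignment:
    out = PatternAlignment(pal.taxa, pal.patterns, w, pal.site_to_pattern,
                           pal.alphabet)
    cache = getattr(pal, "_leaf_partial_cache", None)
    if cache is not None:
        out._leaf_partial_cache = cache
    return out


def fit_mast(aln, topologies: list[Tree], modelspec="JC",
             linkage: str = "linked-model", tol: float = 1e-4,
             max_rounds: int = 200,
             model_update_every: int = 3) -> MastFit:
    """Fit tree weights, per-tree branch lengths and the substitution
    model for a mixture over fixed topologies."""
    if linkage not in ("linked-model", "unlinked-model"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if not topologies:
        raise ValueError("need at least one topology")
    pal = aln if isinstance(aln, PatternAlignment) else compress_patterns(aln)
    aln_taxa = set(pal.taxa)
    for t in topologies:
        missing = aln_taxa - set(t.leaf_names())
        if missing:
            raise ValueError(f"topology missing taxon {sorted(missing)[0]!r}")

    m = len(topologies)

    def prep_tree(t: Tree) -> tuple[Tree, bool]:
        w, _ = t.copy()
        w.unroot()
        has_lengths = all(e.length > 0 for e in w.edges())
        return w, has_lengths

    prepped = [prep_tree(t) for t in topologies]
    # symmetry breaking for branch-length mixtures (GHOST): identical
    # topologies with identical lengths would keep EM at the symmetric
    # fixed point, so duplicates start from deterministically scaled lengths
    for i in range(len(prepped)):
        for j in range(i + 1, len(prepped)):
            ti, tj = prepped[i][0], prepped[j][0]
            if prepped[i][1] and prepped[j][1] and \
                    ti.same_unrooted_topology(tj):
                li = sorted(e.length for e in ti.edges())
                lj = sorted(e.length for e in tj.edges())
                if np.allclose(li, lj, rtol=1e-9, atol=1e-12):
                    factor = 2.0 ** (j - i)
                    for e in tj.edges():
                        e.length = min(e.length * factor, 9.9)
    if isinstance(modelspec, MixtureModel):
        spec = None
        base_model = modelspec
        trees = []
        for w, has_lengths in prepped:
            if not has_lengths:
                w, _lnl = optimize_branch_lengths(w, pal, base_model, tol=tol)
            trees.append(w)
        models = [base_model] * m
        template = None
        n_model_free = 0
    else:
        spec = parse_model_string(modelspec) if isinstance(modelspec, str) else modelspec
        template = MixtureTemplate(spec, pal.expand())
        n_model_free = template.counted_free(0, include_weights=False)
        trees, fits = [], []
        for w, has_lengths in prepped:
            # input branch lengths, when present, are the EM starting
            # point; refitting them on the pooled data would collapse the
            # distinguishing branches before the E-step can separate sites
            fit = optimize_model(w, pal, spec, tol=max(tol, 1e-3),
                                 optimize_branches=not has_lengths)
            fits.append(fit)
            trees.append(fit.tree)
        if linkage == "linked-model":
            best = int(np.argmax([f.lnl for f in fits]))
            models = [fits[best].mixture] * m
            model_x = [fits[best].extras["x"].copy()] * m
        else:
            models = [f.mixture for f in fits]
            model_x = [f.extras["x"].copy() for f in fits]

    lam = np.full(m, 1.0 / m)
    w_pat = pal.weights
    n_eff = float(w_pat.sum())

    def tree_lnls() -> np.ndarray:
        return np.stack([site_log_likelihoods(trees[t], pal, models[t]).pattern_lnl
                         for t in range(m)])

    L = tree_lnls()
    with np.errstate(divide="ignore"):
        total = float(w_pat @ logsumexp(L + np.log(lam)[:, None], axis=0))
    trace = [total]
    converged = False
    for rnd in range(max_rounds):
        # E-step + weight updates iterated to convergence (L fixed, so
        # each sub-iteration is itself a monotone EM step on lambda)
        for _sub in range(100):
            with np.errstate(divide="ignore"):
                logpost = L + np.log(np.maximum(lam, 1e-300))[:, None]
            logpost -= logsumexp(logpost, axis=0, keepdims=True)
            gamma = np.exp(logpost)                  # (m, n_pat)
            new_lam = (gamma @ w_pat) / n_eff
            new_lam = np.clip(new_lam, 1e-10, None)
            new_lam /= new_lam.sum()
            moved = float(np.max(np.abs(new_lam - lam)))
            lam = new_lam
            if moved < 1e-8:
                break
        # M-step: branch lengths on posterior-weighted data
        for t in range(m):
            wp = _weighted_pal(pal, w_pat * gamma[t])
            trees[t], _ = optimize_branch_lengths(trees[t], wp, models[t],
                                                  tol=tol, max_sweeps=1)
        # M-step: model parameters (generalized EM, every few rounds)
        if template is not None and template.n_params and \
                (rnd + 1) % model_update_every == 0:
            from scipy.optimize import minimize
            if linkage == "linked-model":
                def neg(xv):
                    mix = template.build(xv)
                    Lx = np.stack([
                        site_log_likelihoods(trees[t], pal, mix).pattern_lnl
                        for t in range(m)])
                    with np.errstate(divide="ignore"):
                        return -float(w_pat @ logsumexp(
                            Lx + np.log(lam)[:, None], axis=0))
                res = minimize(neg, model_x[0], method="L-BFGS-B",
                               bounds=template.bounds(),
                               options={"maxiter": 15, "ftol": 1e-9})
                cur = -neg(model_x[0])
                if -res.fun > cur:
                    model_x = [res.x.copy()] * m
                    models = [template.build(res.x)] * m
            else:
                for t in range(m):
                    wp = _weighted_pal(pal, w_pat * gamma[t])

                    def neg_t(xv, t=t, wp=wp):
                        return -site_log_likelihoods(
                            trees[t], wp, template.build(xv)).total
                    res = minimize(neg_t, model_x[t], method="L-BFGS-B",
                                   bounds=template.bounds(),
                                   options={"maxiter": 15, "ftol": 1e-9})
                    if -res.fun > -neg_t(model_x[t]):
                        model_x[t] = res.x.copy()
                        models[t] = template.build(res.x)
        L = tree_lnls()
        with np.errstate(divide="ignore"):
            new_total = float(w_pat @ logsumexp(L + np.log(lam)[:, None], axis=0))
        trace.append(new_total)
        if new_total - total < tol:
            total = max(total, new_total)
            converged = True
            break
        total = new_total

    with np.errstate(divide="ignore"):
        logpost = L + np.log(np.maximum(lam, 1e-300))[:, None]
    logpost -= logsumexp(logpost, axis=0, keepdims=True)
    gamma = np.exp(logpost).T                        # (n_pat, m)

    # weight identifiability across isomorphic topologies
    groups = []
    seen = set()
    for i in range(m):
        if i in seen:
            continue
        grp = [i]
        for j in range(i + 1, m):
            if j not in seen and trees[i].same_unrooted_topology(trees[j]):
                grp.append(j)
                seen.add(j)
        if len(grp) > 1:
            groups.append(grp)
            warnings.warn(
                f"topologies {grp} are isomorphic; only their summed weight "
                f"{lam[grp].sum():.4f} is identifiable")

    n_branch = sum(len(t.edges()) for t in trees)
    n_models = n_model_free if (template is None or linkage == "linked-model") \
        else n_model_free * m
    p = (m - 1) + n_branch + n_models
    return MastFit(trees, lam, models, total, gamma, pal.site_to_pattern,
                   trace, converged, groups, p)


def site_assignments(fit: MastFit) -> np.ndarray:
    """Per-site posterior probability over trees, rows summing to one."""
    return fit.pattern_posteriors[fit.site_to_pattern]
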