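"""Information criteria and automatic mixture-class selection.

`mixture_finder` grows a DNA matrix mixture one class at a time:
start from the best single-class model among the candidates, seed each
proposed extra class from the quartile of sites the current fit explains
worst, re-optimize the full mixture, and keep the extra class only if
the information criterion improves. Selection stops at the first
rejection or at ``k_max`` classes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, compress_patterns
from .distance import ml_pairwise_distances, nj_tree
from .fitting import optimize_model
from .likelihood import FitResult
from .modelspec import ModelSpec, parse_model_string
from .trees import Tree

__all__ = ["SelectionRecord", "information_criteria", "mixture_finder",
           "DEFAULT_CANDIDATES"]

DEFAULT_CANDIDATES = ("JC", "K2P", "HKY", "GTR",
                      "JC+G4", "K2P+G4", "HKY+G4", "GTR+G4")


@dataclass
class SelectionRecord:
    label: str
    lnl: float
    p: int
    n: int
    aic: float
    aicc: float | None
    bic: float
    accepted: bool = False

    def criterion(self, name: str) -> float:
        name = name.upper()
        if name == "AIC":
            return self.aic
        if name == "AICC":
            return np.inf if self.aicc is None else self.aicc
        if name == "BIC":
            return self.bic
        raise ValueError(f"unknown criterion {name!r}")


def information_criteria(lnl: float, p: int, n: int,
                         label: str = "") -> SelectionRecord:
    """AIC, small-sample AICc and BIC from a fit summary.

    AICc is undefined (None) when n <= p + 1.
    """
    aic = -2.0 * lnl + 2.0 * p
    aicc = aic + 2.0 * p * (p + 1) / (n - p - 1) if n > p + 1 else None
    bic = -2.0 * lnl + p * np.log(n)
    return SelectionRecord(label, lnl, p, n, aic, aicc, bic)


def _record(fit: FitResult, label: str, n: int) -> SelectionRecord:
    return information_criteria(fit.lnl, fit.n_free_params, n, label)


def mixture_finder(aln: Alignment, candidates=DEFAULT_CANDIDATES,
                   criterion: str = "BIC", k_max: int = 10,
                   tree: Tree | None = None, tol: float = 1e-3,
                   worst_fraction: float = 0.25,
                   new_class_weight: float = 0.1,
                   max_rounds: int = 15, lbfgs_maxiter: int = 10,
                   em_iterations: int = 6) -> FitResult:
    """Select the number of DNA mixture classes and their models.

    Returns the accepted fit; the full selection trace (one
    `SelectionRecord` per evaluated candidate, accepted steps flagged)
    is in ``result.extras["selection_trace"]``.
    """
    if aln.alphabet.size != 4:
        raise ValueError("mixture-class selection is defined for DNA data only")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    pal = compress_patterns(aln)
    n = aln.n_sites
    if tree is None:
        tree = nj_tree(ml_pairwise_distances(aln))

    trace: list[SelectionRecord] = []

    def _with_fo(spec: ModelSpec) -> ModelSpec:
        # per-class ML frequencies: same parameter count as empirical
        # counts but lets mixture classes separate in base composition
        return ModelSpec(spec.classes, "FO", spec.invariant, spec.rate_kind,
                         spec.rate_categories, spec.gamma_alpha)

    # step 1: best single-class model
    best_fit, best_rec = None, None
    for cand in candidates:
        fit = optimize_model(tree, pal, _with_fo(parse_model_string(cand)),
                             tol=tol, max_rounds=max_rounds,
                             lbfgs_maxiter=lbfgs_maxiter,
                             em_iterations=em_iterations)
        rec = _record(fit, cand, n)
        trace.append(rec)
        if best_rec is None or rec.criterion(criterion) < best_rec.criterion(criterion):
            best_fit, best_rec = fit, rec
    best_rec.accepted = True
    spec = _with_fo(parse_model_string(best_rec.label))
    class_specs = list(spec.classes)
    weights = np.array([1.0])

    # stepwise class additions
    while len(class_specs) < k_max:
        site_lnl = best_fit.sites.site_lnl()
        n_worst = max(4, int(round(worst_fraction * n)))
        worst = np.argsort(site_lnl)[:n_worst]
        sub = aln.subset_sites(np.sort(worst))

        # choose the new class's matrix on the worst-explained sites
        best_sub = None
        seen = set()
        for cand in candidates:
            base = parse_model_string(cand).classes[0]
            if base in seen:
                continue
            seen.add(base)
            sub_spec = ModelSpec((base,), spec.freq_option, spec.invariant,
                                 spec.rate_kind, spec.rate_categories,
                                 spec.gamma_alpha)
            sub_fit = optimize_model(best_fit.tree, sub, sub_spec, tol=tol,
                                     optimize_branches=False,
                                     max_rounds=max_rounds,
                                     lbfgs_maxiter=lbfgs_maxiter,
                                     em_iterations=em_iterations)
            sub_rec = _record(sub_fit, sub_spec.canonical(), sub.n_sites)
            if best_sub is None or sub_rec.criterion(criterion) < best_sub[1].criterion(criterion):
                best_sub = (base, sub_rec)
        new_base = best_sub[0]

        cand_classes = class_specs + [new_base]
        cand_spec = ModelSpec(tuple(cand_classes), spec.freq_option,
                              spec.invariant, spec.rate_kind,
                              spec.rate_categories, spec.gamma_alpha)
        w0 = np.concatenate([weights * (1.0 - new_class_weight),
                             [new_class_weight]])
        fit = optimize_model(best_fit.tree, pal, cand_spec, tol=tol,
                             weights0=w0, max_rounds=max_rounds,
                             lbfgs_maxiter=lbfgs_maxiter,
                             em_iterations=em_iterations)
        rec = _record(fit, cand_spec.canonical(), n)
        trace.append(rec)
        if rec.criterion(criterion) < best_rec.criterion(criterion):
            rec.accepted = True
            best_fit, best_rec = fit, rec
            class_specs = cand_classes
            weights = fit.extras["weights"]
        else:
            break

    best_fit.extras["selection_trace"] = trace
    best_fit.extras["selected_k"] = len(class_specs)
    best_fit.extras["criterion"] = criterion.upper()
    return best_fit
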