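"""Maximum-likelihood model fitting.

A `MixtureTemplate` maps a parsed model string onto an unconstrained
parameter vector (log exchangeabilities / rates, logit frequencies,
log gamma shape, free-rate raws) and rebuilds a `MixtureModel` from any
such vector. `optimize_model` alternates three monotone steps until the
log-likelihood gain over a round falls below tolerance:

1. EM updates of the mixture class weights (expected pattern memberships
   normalized over sites),
2. bounded quasi-Newton (L-BFGS-B) over the continuous model parameters,
3. coordinate-wise branch-length sweeps.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .alignment import Alignment, PatternAlignment, compress_patterns
from .modelspec import ClassSpec, ModelSpec, parse_model_string
from .ratedist import (RateDistribution, add_invariant, discrete_gamma_rates,
                       make_free_rates, single_rate)
from .submodels import (MixtureModel, SubstitutionModel, gtr, hky, jc, k2p,
                        named_matrix, poisson, read_nonreversible_matrix,
                        read_paml_matrix, unrest)
from .likelihood import (FitResult, log_likelihood, optimize_branch_lengths,
                         site_log_likelihoods)
from .trees import Tree

__all__ = ["MixtureTemplate", "optimize_model", "count_free_parameters"]

_LOG_BOUND = (np.log(1e-3), np.log(1e3))
_ALPHA_BOUND = (np.log(0.02), np.log(100.0))


def _softmax_from_raw(raw: np.ndarray) -> np.ndarray:
    z = np.concatenate([raw, [0.0]])
    z = np.exp(z - z.max())
    return z / z.sum()


class _BaseBlock:
    """Free substitution-matrix parameters of one mixture class."""

    def __init__(self, cls: ClassSpec, freq_option: str, emp_freqs: np.ndarray):
        self.cls = cls
        base = cls.base
        self.fixed_model: SubstitutionModel | None = None
        self.n_matrix = {"JC": 0, "K2P": 1, "HKY": 1, "GTR": 5, "UNREST": 11,
                         "POISSON": 0}.get(base, 0)
        if base == "QFILE":
            self.fixed_model = read_paml_matrix(cls.matrix_path)
        elif base == "NONREVFILE":
            self.fixed_model = read_nonreversible_matrix(cls.matrix_path)
        elif base in ("LG", "WAG", "JTT"):
            self.fixed_model = named_matrix(base)

        # frequency handling
        if base in ("JC", "K2P", "POISSON"):
            self.freq_mode = "uniform"
        elif self.fixed_model is not None:
            self.freq_mode = {"default": "file", "F": "empirical",
                              "FO": "optimized", "FQ": "uniform"}[freq_option]
        else:
            self.freq_mode = {"default": "empirical", "F": "empirical",
                              "FO": "optimized", "FQ": "uniform"}[freq_option]
        if base == "UNREST":
            self.freq_mode = "stationary"
        self.emp_freqs = emp_freqs
        s = emp_freqs.shape[0]
        self.n_freq = (s - 1) if self.freq_mode == "optimized" else 0

    @property
    def n_params(self) -> int:
        return self.n_matrix + self.n_freq

    def counted_free(self) -> int:
        """Parameters tallied for information criteria: optimized ones plus
        empirical frequencies (estimated from data, standard convention)."""
        n = self.n_matrix + self.n_freq
        if self.freq_mode == "empirical":
            n += self.emp_freqs.shape[0] - 1
        return n

    def x0(self) -> np.ndarray:
        x = np.zeros(self.n_matrix)  # log scale: all rates start at 1
        if self.cls.base in ("K2P", "HKY"):
            x[0] = np.log(2.0)
        if self.n_freq:
            f = np.clip(self.emp_freqs, 1e-4, None)
            x = np.concatenate([x, np.log(f[:-1] / f[-1])])
        return x

    def bounds(self) -> list[tuple[float, float]]:
        b = [_LOG_BOUND] * self.n_matrix
        b += [(-12.0, 12.0)] * self.n_freq
        return b

    def build(self, x: np.ndarray) -> SubstitutionModel:
        base = self.cls.base
        if self.freq_mode == "uniform":
            s = self.emp_freqs.shape[0]
            freqs = np.full(s, 1.0 / s)
        elif self.freq_mode == "empirical":
            freqs = self.emp_freqs
        elif self.freq_mode == "optimized":
            freqs = _softmax_from_raw(x[self.n_matrix:])
        elif self.freq_mode == "file":
            freqs = self.fixed_model.freqs
        else:  # stationary (nonreversible)
            freqs = None

        if base == "JC":
            return jc()
        if base == "POISSON":
            return poisson()
        if base == "K2P":
            return k2p(float(np.exp(x[0])))
        if base == "HKY":
            return hky(float(np.exp(x[0])), freqs)
        if base == "GTR":
            rates = np.concatenate([np.exp(x[:5]), [1.0]])
            return gtr(rates, freqs)
        if base == "UNREST":
            rates = np.concatenate([np.exp(x[:11]), [1.0]])
            return unrest(rates)
        # fixed-matrix bases: rebuild with the requested frequencies
        fm = self.fixed_model
        if freqs is None or self.freq_mode == "file":
            return fm
        if not fm.reversible:
            return fm
        return SubstitutionModel(fm.alphabet, fm.name,
                                 exchangeabilities=fm.exchangeabilities,
                                 freqs=freqs)


class _RateBlock:
    """Free rate-heterogeneity parameters (shared across classes)."""

    def __init__(self, spec: ModelSpec):
        self.kind = spec.rate_kind
        self.m = spec.rate_categories
        self.fixed_alpha = spec.gamma_alpha
        self.invariant = spec.invariant
        if self.kind is None:
            self.n_params = 0
        elif self.kind == "gamma":
            self.n_params = 0 if self.fixed_alpha is not None else 1
        else:  # freerate: m-1 log rates (first fixed), m-1 weight logits
            self.n_params = 2 * (self.m - 1)
        if self.invariant:
            self.n_params += 1  # logit of p_inv

    def x0(self) -> np.ndarray:
        x = []
        if self.kind == "gamma" and self.fixed_alpha is None:
            x.append(np.log(1.0))
        elif self.kind == "freerate":
            x.extend(np.linspace(0.2, 1.0, self.m - 1))  # log extra rates
            x.extend([0.0] * (self.m - 1))
        if self.invariant:
            x.append(-2.0)  # p_inv ~ 0.12 initially
        return np.asarray(x, float)

    def bounds(self) -> list[tuple[float, float]]:
        b = []
        if self.kind == "gamma" and self.fixed_alpha is None:
            b.append(_ALPHA_BOUND)
        elif self.kind == "freerate":
            b += [(np.log(1e-3), np.log(50.0))] * (self.m - 1)
            b += [(-10.0, 10.0)] * (self.m - 1)
        if self.invariant:
            b.append((-10.0, 5.0))
        return b

    def build(self, x: np.ndarray) -> tuple[RateDistribution, float | None]:
        i = 0
        if self.kind is None:
            base = single_rate()
        elif self.kind == "gamma":
            if self.fixed_alpha is not None:
                alpha = self.fixed_alpha
            else:
                alpha = float(np.exp(x[i]))
                i += 1
            base = discrete_gamma_rates(alpha, self.m)
        else:
            raw_r = np.concatenate([[1.0], np.exp(x[i:i + self.m - 1])])
            i += self.m - 1
            logits = np.concatenate([x[i:i + self.m - 1], [0.0]])
            i += self.m - 1
            w = np.exp(logits - logits.max())
            base = make_free_rates(raw_r, w / w.sum())
        alpha_out = None
        if self.kind == "gamma":
            alpha_out = self.fixed_alpha if self.fixed_alpha is not None \
                else float(np.exp(x[0]))
        if self.invariant:
            p_inv = 1.0 / (1.0 + np.exp(-x[i]))
            base = add_invariant(float(p_inv), base)
        return base, alpha_out


class MixtureTemplate:
    """Packs/unpacks all continuous free parameters of a model string."""

    def __init__(self, spec: ModelSpec | str, alignment: Alignment):
        if isinstance(spec, str):
            spec = parse_model_string(spec)
        self.spec = spec
        emp = alignment.empirical_frequencies()
        self.blocks = [_BaseBlock(c, spec.freq_option, emp) for c in spec.classes]
        self.rate_block = _RateBlock(spec)
        self.offsets = np.cumsum([0] + [b.n_params for b in self.blocks]
                                 + [self.rate_block.n_params])

    @property
    def n_params(self) -> int:
        return int(self.offsets[-1])

    @property
    def k(self) -> int:
        return len(self.blocks)

    def x0(self) -> np.ndarray:
        parts = [b.x0() for b in self.blocks] + [self.rate_block.x0()]
        return np.concatenate(parts) if parts else np.zeros(0)

    def bounds(self) -> list[tuple[float, float]]:
        out = []
        for b in self.blocks:
            out += b.bounds()
        out += self.rate_block.bounds()
        return out

    def build(self, x: np.ndarray, weights=None) -> MixtureModel:
        models = []
        for i, b in enumerate(self.blocks):
            models.append(b.build(x[self.offsets[i]:self.offsets[i + 1]]))
        rates, self.last_alpha = self.rate_block.build(x[self.offsets[-2]:])
        classes = [(m, rates) for m in models]
        return MixtureModel(classes, weights, shared_rates=True,
                            name=self.spec.canonical())

    def counted_free(self, n_branches: int = 0,
                     include_weights: bool = True) -> int:
        n = sum(b.counted_free() for b in self.blocks)
        n += self.rate_block.n_params
        if include_weights:
            n += self.k - 1
        return n + n_branches


def count_free_parameters(spec: ModelSpec | str, alignment: Alignment,
                          n_branches: int) -> int:
    return MixtureTemplate(spec, alignment).counted_free(n_branches)


def optimize_model(tree: Tree, data, spec, *, tol: float = 1e-4,
                   max_rounds: int = 100, optimize_branches: bool = True,
                   em_iterations: int = 10, lbfgs_maxiter: int = 40,
                   weights0=None) -> FitResult:
    """Fit a model string on a fixed topology.

    Alternates mixture-weight EM, L-BFGS-B on the continuous model
    parameters and branch-length sweeps; each step is individually
    monotone, so the trace of log-likelihoods never decreases. A fit
    that exhausts ``max_rounds`` is returned flagged unconverged.
    """
    if isinstance(spec, str):
        spec = parse_model_string(spec)
    pal = data if isinstance(data, PatternAlignment) else compress_patterns(data)
    aln_for_freqs = pal.expand() if not isinstance(data, Alignment) else data
    template = MixtureTemplate(spec, aln_for_freqs)
    work, _ = tree.copy()

    x = template.x0()
    weights = (np.full(template.k, 1.0 / template.k)
               if weights0 is None else np.asarray(weights0, float))
    mixture = template.build(x, weights)
    lnl = log_likelihood(work, pal, mixture)
    if not np.isfinite(lnl):
        raise ValueError("non-finite starting log-likelihood: data/model mismatch?")
    trace = [("init", lnl)]
    converged = False
    for _round in range(max_rounds):
        round_start = lnl

        # EM on class weights
        if template.k > 1:
            for _ in range(em_iterations):
                sl = site_log_likelihoods(work, pal, template.build(x, weights))
                post = sl.class_posteriors()  # (n_pat, k)
                new_w = (pal.weights @ post) / pal.weights.sum()
                new_w = np.clip(new_w, 1e-8, None)
                weights = new_w / new_w.sum()
            mixture = template.build(x, weights)
            lnl = log_likelihood(work, pal, mixture)
            trace.append(("weights", lnl))

        # continuous model parameters
        if template.n_params:
            def neg(xv):
                try:
                    return -log_likelihood(work, pal, template.build(xv, weights))
                except (ValueError, FloatingPointError):
                    return 1e12

            res = minimize(neg, x, method="L-BFGS-B",
                           bounds=template.bounds(),
                           options={"maxiter": lbfgs_maxiter, "ftol": 1e-10})
            if -res.fun > lnl:
                x, lnl = res.x, -res.fun
            trace.append(("model", lnl))

        # branch lengths
        if optimize_branches:
            mixture = template.build(x, weights)
            work, bl_lnl = optimize_branch_lengths(work, pal, mixture,
                                                   tol=tol, max_sweeps=2)
            lnl = max(lnl, bl_lnl)
            trace.append(("branches", lnl))

        if lnl - round_start < tol:
            converged = True
            break

    mixture = template.build(x, weights).canonicalized()
    sites = site_log_likelihoods(work, pal, mixture)
    n_branches = len(work.edges()) if optimize_branches else 0
    p = template.counted_free(n_branches)
    return FitResult(lnl=sites.total, mixture=mixture, tree=work,
                     n_free_params=p, sites=sites, trace=trace,
                     converged=converged, model_string=spec.canonical(),
                     extras={"x": x, "weights": weights,
                             "alpha": getattr(template, "last_alpha", None),
                             "template": template})
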