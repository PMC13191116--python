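"""Substitution models: normalized rate matrices and transition probabilities.

Reversible models are parameterized by symmetric exchangeabilities R and
stationary frequencies pi, with Q_ij = R_ij * pi_j off-diagonal.
Nonreversible models carry a full off-diagonal rate specification; their
stationary distribution is computed from Q and used as the default root
frequency. Every matrix is normalized so one unit of branch length equals
one expected substitution per site: -sum_i pi_i q_ii = 1.

Transition probabilities use an eigendecomposition of the pi^(1/2)
similarity-symmetrized matrix for reversible models and scaling-and-
squaring (scipy expm) for nonreversible ones.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
from scipy.linalg import expm

from .alphabet import AA, DNA, Alphabet
from .ratedist import RateDistribution, single_rate

__all__ = ["SubstitutionModel", "MixtureModel", "build_rate_matrix",
           "jc", "k2p", "hky", "gtr", "unrest", "poisson",
           "read_paml_matrix", "write_paml_matrix", "read_nonreversible_matrix",
           "named_matrix",
           "stationary_distribution", "is_reversible"]

_FREQ_TOL = 1e-8


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Left null vector of Q on the probability simplex."""
    s = Q.shape[0]
    A = np.vstack([Q.T, np.ones(s)])
    b = np.zeros(s + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def is_reversible(Q: np.ndarray, pi: np.ndarray, tol: float = 1e-10) -> bool:
    """Detailed-balance check pi_i q_ij == pi_j q_ji."""
    F = pi[:, None] * Q
    return bool(np.max(np.abs(F - F.T)) <= tol)


class SubstitutionModel:
    """A single normalized CTMC substitution model.

    Parameters
    ----------
    alphabet : DNA or AA alphabet.
    exchangeabilities : symmetric (s, s) matrix (reversible models) or None.
    freqs : stationary frequencies; required for reversible models,
        derived from the rate matrix when nonreversible.
    rate_matrix : full off-diagonal rate specification (nonreversible).
    root_freqs : frequencies at the root; defaults to ``freqs``.
    """

    def __init__(self, alphabet: Alphabet, name: str = "custom", *,
                 exchangeabilities: np.ndarray | None = None,
                 freqs: np.ndarray | None = None,
                 rate_matrix: np.ndarray | None = None,
                 root_freqs: np.ndarray | None = None):
        self.alphabet = alphabet
        self.name = name
        s = alphabet.size
        if (exchangeabilities is None) == (rate_matrix is None):
            raise ValueError("give exactly one of exchangeabilities / rate_matrix")

        if exchangeabilities is not None:
            R = np.asarray(exchangeabilities, float)
            if R.shape != (s, s) or np.max(np.abs(R - R.T)) > 1e-12:
                raise ValueError("exchangeabilities must be symmetric (s, s)")
            off = R[~np.eye(s, dtype=bool)]
            if np.any(off < 0):
                raise ValueError("negative exchangeability")
            if freqs is None:
                raise ValueError("reversible model requires frequencies")
            pi = np.asarray(freqs, float)
            if abs(pi.sum() - 1.0) > _FREQ_TOL or np.any(pi < 0):
                raise ValueError("frequencies must be non-negative and sum to 1")
            pi = pi / pi.sum()
            Q = R * pi[None, :]
            np.fill_diagonal(Q, 0.0)
            self.reversible = True
            self.exchangeabilities = R
        else:
            Q = np.array(rate_matrix, float)
            if Q.shape != (s, s):
                raise ValueError("rate matrix must be (s, s)")
            offmask = ~np.eye(s, dtype=bool)
            if np.any(Q[offmask] < 0):
                raise ValueError("negative off-diagonal rate")
            np.fill_diagonal(Q, 0.0)
            self.reversible = False
            self.exchangeabilities = None
            pi = None

        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        if pi is None:
            pi = stationary_distribution(Q)
        mu = -float(pi @ np.diag(Q))
        if mu <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        self.Q = Q / mu
        self.scale = mu
        self.freqs = pi
        self.root_freqs = pi if root_freqs is None else np.asarray(root_freqs, float)
        if abs(self.root_freqs.sum() - 1.0) > _FREQ_TOL:
            raise ValueError("root frequencies must sum to 1")
        self._prepare_decomposition()

    def _prepare_decomposition(self):
        if self.reversible and np.all(self.freqs > 0):
            d = np.sqrt(self.freqs)
            B = (self.Q * d[:, None]) / d[None, :]
            B = 0.5 * (B + B.T)
            lam, U = np.linalg.eigh(B)
            self._eig = (lam, U / d[None, :] * 1.0, None)
            # P(t) = diag(1/d) U exp(lam t) U^T diag(d)
            self._left = U.T * d[None, :]
            self._right = U / d[:, None]
        else:
            self._eig = None

    def transition_probabilities(self, t: float) -> np.ndarray:
        """Stochastic matrix P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        if self._eig is not None:
            lam = self._eig[0]
            P = (self._right * np.exp(lam * t)[None, :]) @ self._left
        else:
            P = expm(self.Q * t)
        # clamp tiny negative round-off
        np.clip(P, 0.0, 1.0, out=P)
        rs = P.sum(axis=1, keepdims=True)
        return P / rs

    def dtransition(self, t: float) -> np.ndarray:
        """d/dt exp(Qt) = Q exp(Qt)."""
        return self.Q @ self.transition_probabilities(t)

    def detailed_balance_residual(self) -> float:
        F = self.freqs[:, None] * self.Q
        return float(np.max(np.abs(F - F.T)))

    def __repr__(self):
        kind = "reversible" if self.reversible else "nonreversible"
        return f"<SubstitutionModel {self.name} ({kind}, {self.alphabet.name})>"


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """The normalized instantaneous rate matrix of a model."""
    return model.Q


class MixtureModel:
    """Weighted classes, each a (substitution model, rate distribution) pair."""

    def __init__(self, classes, weights=None, shared_rates: bool = False,
                 name: str | None = None):
        self.classes = [(m, r if r is not None else single_rate())
                        for m, r in classes]
        k = len(self.classes)
        if k < 1:
            raise ValueError("need at least one class")
        w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, float)
        if w.shape != (k,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("class weights must be a probability vector")
        self.weights = w / w.sum()
        self.shared_rates = shared_rates
        self.name = name or "+".join(m.name for m, _ in self.classes)

    @classmethod
    def single(cls, model: SubstitutionModel,
               rates: RateDistribution | None = None) -> "MixtureModel":
        return cls([(model, rates or single_rate())], np.array([1.0]))

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def alphabet(self) -> Alphabet:
        return self.classes[0][0].alphabet

    def components(self):
        """Flattened (class_idx, model, rate, total_weight) tuples over
        class x rate-category combinations."""
        out = []
        for c, ((m, rd), om) in enumerate(zip(self.classes, self.weights)):
            for r, w in zip(rd.rates, rd.weights):
                out.append((c, m, float(r), float(om * w)))
        return out

    def canonicalized(self) -> "MixtureModel":
        """Classes sorted by weight descending, ties by model name."""
        order = sorted(range(self.n_classes),
                       key=lambda c: (-self.weights[c], self.classes[c][0].name))
        return MixtureModel([self.classes[c] for c in order],
                            self.weights[list(order)],
                            self.shared_rates, self.name)


# ---------------------------------------------------------------------------
# named model constructors
# ---------------------------------------------------------------------------

def _sym_from_upper(alphabet: Alphabet, pairs: dict[tuple[int, int], float],
                    default: float = 1.0) -> np.ndarray:
    s = alphabet.size
    R = np.full((s, s), default)
    np.fill_diagonal(R, 0.0)
    for (i, j), v in pairs.items():
        R[i, j] = R[j, i] = v
    return R


def jc(alphabet: Alphabet = DNA) -> SubstitutionModel:
    s = alphabet.size
    R = np.ones((s, s)) - np.eye(s)
    return SubstitutionModel(alphabet, "JC", exchangeabilities=R,
                             freqs=np.full(s, 1.0 / s))


def k2p(kappa: float = 2.0) -> SubstitutionModel:
    return hky(kappa, np.full(4, 0.25), name="K2P")


def hky(kappa: float = 2.0, freqs=None, name: str = "HKY") -> SubstitutionModel:
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    freqs = np.full(4, 0.25) if freqs is None else np.asarray(freqs, float)
    # transitions: A<->G (0,2), C<->T (1,3)
    R = _sym_from_upper(DNA, {(0, 2): kappa, (1, 3): kappa})
    return SubstitutionModel(DNA, name, exchangeabilities=R, freqs=freqs)


_GTR_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT


def gtr(rates, freqs) -> SubstitutionModel:
    """GTR; ``rates`` are the six exchangeabilities in AC, AG, AT, CG, CT, GT order."""
    rates = np.asarray(rates, float)
    if rates.shape != (6,):
        raise ValueError("GTR needs six exchangeabilities")
    R = _sym_from_upper(DNA, dict(zip(_GTR_PAIRS, rates)))
    return SubstitutionModel(DNA, "GTR", exchangeabilities=R,
                             freqs=np.asarray(freqs, float))


def unrest(off_diagonal_rates, root_freqs=None) -> SubstitutionModel:
    """Fully nonreversible DNA model; 12 off-diagonal rates in row-major
    order (AC, AG, AT, CA, CG, CT, GA, GC, GT, TA, TC, TG)."""
    r = np.asarray(off_diagonal_rates, float)
    if r.shape != (12,):
        raise ValueError("UNREST needs 12 off-diagonal rates")
    Q = np.zeros((4, 4))
    Q[~np.eye(4, dtype=bool)] = r
    return SubstitutionModel(DNA, "UNREST", rate_matrix=Q, root_freqs=root_freqs)


def poisson() -> SubstitutionModel:
    s = AA.size
    R = np.ones((s, s)) - np.eye(s)
    return SubstitutionModel(AA, "POISSON", exchangeabilities=R,
                             freqs=np.full(s, 1.0 / s))


# ---------------------------------------------------------------------------
# matrix files (PAML dialect)
# ---------------------------------------------------------------------------

def _tokens(text: str) -> list[float]:
    return [float(tok) for tok in text.split()]


def read_paml_matrix(path, name: str | None = None) -> SubstitutionModel:
    """Reversible matrix file: lower-triangle exchangeabilities then
    frequencies, whitespace separated (PAML .dat dialect). The alphabet
    (DNA or amino acid) is inferred from the token count."""
    vals = _tokens(Path(path).read_text())
    for alphabet in (AA, DNA):
        s = alphabet.size
        n_tri = s * (s - 1) // 2
        if len(vals) == n_tri + s:
            break
    else:
        raise ValueError(f"{path}: token count {len(vals)} fits neither DNA nor AA layout")
    R = np.zeros((s, s))
    k = 0
    for i in range(1, s):
        for j in range(i):
            R[i, j] = R[j, i] = vals[k]
            k += 1
    freqs = np.asarray(vals[k:], float)
    freqs = freqs / freqs.sum()
    return SubstitutionModel(alphabet, name or Path(path).stem,
                             exchangeabilities=R, freqs=freqs)


def write_paml_matrix(model: SubstitutionModel, path, precision: int = 8) -> None:
    if not model.reversible:
        raise ValueError("PAML lower-triangle format is for reversible models")
    R, pi = model.exchangeabilities, model.freqs
    s = model.alphabet.size
    lines = []
    for i in range(1, s):
        lines.append(" ".join(f"{R[i, j]:.{precision}g}" for j in range(i)))
    lines.append("")
    lines.append(" ".join(f"{p:.{precision}g}" for p in pi))
    Path(path).write_text("\n".join(lines) + "\n")


def read_nonreversible_matrix(path, name: str | None = None) -> SubstitutionModel:
    """Nonreversible matrix file: full off-diagonal rates, row-major."""
    vals = _tokens(Path(path).read_text())
    for alphabet in (AA, DNA):
        s = alphabet.size
        if len(vals) == s * (s - 1):
            break
    else:
        raise ValueError(f"{path}: token count {len(vals)} fits neither DNA nor AA layout")
    Q = np.zeros((s, s))
    Q[~np.eye(s, dtype=bool)] = vals
    return SubstitutionModel(alphabet, name or Path(path).stem, rate_matrix=Q)


_BUNDLED = {"LG", "WAG", "JTT"}


def named_matrix(name: str) -> SubstitutionModel:
    """Bundled published amino-acid matrices (LG, WAG, JTT)."""
    key = name.upper()
    if key not in _BUNDLED:
        raise ValueError(f"no bundled matrix named {name!r}")
    ref = resources.files("phylomix.data") / f"{key}.dat"
    with resources.as_file(ref) as p:
        return read_paml_matrix(p, name=key)
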