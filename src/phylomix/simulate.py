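"""Alignment simulation along a tree under (mixture) substitution models.

Two per-branch algorithms with identical sampling law:

* ``matrix`` — each child state drawn from the parent state's row of
  P(t); cost independent of divergence, preferred for long branches.
* ``events`` — per-site Gillespie simulation (exponential waiting times,
  jump probabilities proportional to off-diagonal rates); cost scales
  with the number of substitutions, preferred for short branches.

``adaptive`` picks per branch: events when the expected number of
substitutions per site is below the switch threshold ``theta``, matrix
otherwise.

Site class and rate-category assignments are drawn once at the root and
inherited down the tree, matching the data-generating process the
mixture likelihood assumes. Each branch consumes its own RNG stream
derived from (seed, branch identifier), so edits elsewhere in the tree
do not perturb a branch's draws.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .likelihood import edge_name
from .submodels import MixtureModel, SubstitutionModel
from .trees import Tree

__all__ = ["SimulationConfig", "simulate", "evolve_branch_matrix",
           "evolve_branch_events", "choose_algorithm"]

DEFAULT_THETA = 0.1


@dataclass
class SimulationConfig:
    tree: Tree
    mixture: MixtureModel
    n_sites: int
    seed: int
    root_sequence: str | None = None
    algorithm: str = "adaptive"      # matrix | events | adaptive
    theta: float = DEFAULT_THETA
    algorithm_log: dict = field(default_factory=dict)  # branch name -> choice

    def __post_init__(self):
        if isinstance(self.mixture, SubstitutionModel):
            self.mixture = MixtureModel.single(self.mixture)
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        if self.theta <= 0:
            raise ValueError("switch threshold must be positive")
        if self.algorithm not in ("matrix", "events", "adaptive"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


def choose_algorithm(expected_substitutions: float, theta: float = DEFAULT_THETA) -> str:
    """events below the switch threshold, matrix above."""
    if expected_substitutions < 0:
        raise ValueError("expected substitutions must be non-negative")
    return "events" if expected_substitutions < theta else "matrix"


def _stream(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode())]))


def evolve_branch_matrix(parent_states: np.ndarray, model: SubstitutionModel,
                         t: float, rng: np.random.Generator) -> np.ndarray:
    """Sample child states from the rows of P(t)."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    P = model.transition_probabilities(t)
    child = parent_states.copy()
    s = model.alphabet.size
    for a in range(s):
        idx = np.nonzero(parent_states == a)[0]
        if idx.size:
            child[idx] = rng.choice(s, size=idx.size, p=P[a])
    return child


def evolve_branch_events(parent_states: np.ndarray, model: SubstitutionModel,
                         t, rng: np.random.Generator) -> np.ndarray:
    """Gillespie simulation per site; ``t`` may be scalar or per-site."""
    t = np.broadcast_to(np.asarray(t, float), parent_states.shape).copy()
    if np.any(t < 0):
        raise ValueError("branch length must be non-negative")
    Q = model.Q
    s = model.alphabet.size
    exit_rate = -np.diag(Q)
    jump = Q / np.maximum(exit_rate[:, None], 1e-300)
    np.fill_diagonal(jump, 0.0)
    jump_cdf = np.cumsum(jump, axis=1)

    states = parent_states.copy()
    remaining = t.copy()
    active = np.arange(states.size)
    while active.size:
        lam = exit_rate[states[active]]
        waits = np.full(active.size, np.inf)
        pos = lam > 0
        waits[pos] = rng.exponential(1.0 / lam[pos])
        hit = waits < remaining[active]
        idx = active[hit]
        remaining[idx] -= waits[hit]
        if idx.size:
            u = rng.random(idx.size)
            rows = jump_cdf[states[idx]]
            states[idx] = (u[:, None] > rows).sum(axis=1).clip(max=s - 1)
        active = idx
    return states


def simulate(config: SimulationConfig) -> Alignment:
    """Evolve a root sequence down the tree; returns the leaf alignment.

    Deterministic in the config (including the seed); the per-branch
    algorithm decisions are recorded in ``config.algorithm_log``.
    """
    mixture = config.mixture
    alphabet = mixture.alphabet
    n = config.n_sites
    k = mixture.n_classes

    root_rng = _stream(config.seed, "root")
    site_class = root_rng.choice(k, size=n, p=mixture.weights)
    site_rate = np.empty(n)
    for c, (_m, rd) in enumerate(mixture.classes):
        idx = np.nonzero(site_class == c)[0]
        if idx.size:
            cats = root_rng.choice(rd.n_categories, size=idx.size, p=rd.weights)
            site_rate[idx] = rd.rates[cats]

    if config.root_sequence is not None:
        seq = config.root_sequence.upper()
        if len(seq) != n:
            raise ValueError(f"root sequence length {len(seq)} != {n} sites")
        bad = [ch for ch in set(seq) if ch not in alphabet.states]
        if bad:
            raise ValueError(f"root sequence symbol {bad[0]!r} outside alphabet")
        lut = {ch: i for i, ch in enumerate(alphabet.states)}
        root_states = np.array([lut[ch] for ch in seq], dtype=np.int64)
    else:
        root_states = np.empty(n, dtype=np.int64)
        for c, (model, _rd) in enumerate(mixture.classes):
            idx = np.nonzero(site_class == c)[0]
            if idx.size:
                root_states[idx] = root_rng.choice(
                    alphabet.size, size=idx.size, p=model.root_freqs)

    clades = config.tree.clades()
    states: dict[int, np.ndarray] = {config.tree.root.uid: root_states}
    for node in config.tree.preorder():
        if node.parent is None:
            continue
        bname = edge_name(node, clades)
        rng = _stream(config.seed, f"branch:{bname}")
        t = node.length
        if config.algorithm == "adaptive":
            algo = choose_algorithm(t, config.theta)
        else:
            algo = config.algorithm
        config.algorithm_log[bname] = algo
        parent = states[node.parent.uid]
        child = parent.copy()
        for c, (model, _rd) in enumerate(mixture.classes):
            cidx = np.nonzero(site_class == c)[0]
            if not cidx.size:
                continue
            if algo == "events":
                child[cidx] = evolve_branch_events(
                    parent[cidx], model, t * site_rate[cidx], rng)
            else:
                # matrix algorithm needs one P per distinct site rate
                for r in np.unique(site_rate[cidx]):
                    ridx = cidx[site_rate[cidx] == r]
                    child[ridx] = evolve_branch_matrix(
                        parent[ridx], model, t * float(r), rng)
        states[node.uid] = child

    leaves = config.tree.leaves()
    chars = np.array(list(alphabet.states))
    data = np.stack([chars[states[leaf.uid]] for leaf in leaves])
    return Alignment([leaf.label for leaf in leaves], data, alphabet)
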