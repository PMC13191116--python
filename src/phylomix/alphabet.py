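"""Character alphabets and ambiguity handling for DNA and amino-acid data.

Each alphabet maps every permitted symbol (canonical states, IUPAC
ambiguity codes, gaps) to the subset of states it is compatible with.
Likelihood computations use these subsets directly: an ambiguous leaf
character contributes a partial-likelihood vector with ones on every
compatible state.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Alphabet", "DNA", "AA", "guess_alphabet"]


@dataclass(frozen=True)
class Alphabet:
    name: str
    states: str
    ambiguity: dict[str, str] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.states)

    def __post_init__(self):
        table = {}
        for i, s in enumerate(self.states):
            table[s] = (i,)
        for sym, members in self.ambiguity.items():
            table[sym] = tuple(self.states.index(m) for m in members)
        object.__setattr__(self, "_table", table)
        # symbol -> 0/1 row over states, used to build leaf partials
        rows = {}
        for sym, idx in table.items():
            v = np.zeros(len(self.states))
            v[list(idx)] = 1.0
            rows[sym] = v
        object.__setattr__(self, "_rows", rows)

    def is_valid(self, symbol: str) -> bool:
        return symbol in self._table

    def state_indices(self, symbol: str) -> tuple[int, ...]:
        return self._table[symbol]

    def partial_row(self, symbol: str) -> np.ndarray:
        """0/1 compatibility vector over states for one character."""
        return self._rows[symbol]

    def is_ambiguous(self, symbol: str) -> bool:
        return len(self._table[symbol]) > 1

    def encode(self, seq: str) -> np.ndarray:
        """Characters -> integer codes; ambiguous symbols get codes >= size."""
        symbols = self.symbol_order
        lut = {s: i for i, s in enumerate(symbols)}
        try:
            return np.array([lut[c] for c in seq], dtype=np.int16)
        except KeyError as e:
            raise ValueError(f"symbol {e.args[0]!r} not in {self.name} alphabet") from None

    @property
    def symbol_order(self) -> tuple[str, ...]:
        return tuple(self._table)


_DNA_AMBIG = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "U": "T", "-": "ACGT", "?": "ACGT",
}

_AA_STATES = "ARNDCQEGHILKMFPSTWYV"  # PAML ordering
_AA_AMBIG = {
    "B": "ND", "Z": "EQ", "J": "IL",
    "X": _AA_STATES, "-": _AA_STATES, "?": _AA_STATES, "*": _AA_STATES,
}

DNA = Alphabet("DNA", "ACGT", _DNA_AMBIG)
AA = Alphabet("AA", _AA_STATES, _AA_AMBIG)


def guess_alphabet(symbols) -> Alphabet:
    """DNA if every symbol is a valid DNA character, else amino acid."""
    syms = {s.upper() for s in symbols}
    if all(DNA.is_valid(s) for s in syms):
        return DNA
    if all(AA.is_valid(s) for s in syms):
        return AA
    bad = sorted(s for s in syms if not AA.is_valid(s))
    raise ValueError(f"symbols not valid in any supported alphabet: {bad}")
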