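"""Alignment containers and readers (FASTA, relaxed PHYLIP) with
site-pattern compression.

The likelihood engine never sees raw columns: identical columns are
collapsed into weighted site patterns (`PatternAlignment`), which keeps
the per-site work proportional to the number of *distinct* columns.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO

from .alphabet import Alphabet, guess_alphabet

__all__ = ["Alignment", "PatternAlignment", "read_alignment", "write_alignment",
           "compress_patterns"]


class AlignmentFormatError(ValueError):
    pass


@dataclass
class Alignment:
    """Taxa-by-sites character matrix over a declared alphabet.

    ``data`` is a 2-D array of single uppercase characters, one row per
    taxon. All rows have equal length; taxon names are unique.
    """

    taxa: list[str]
    data: np.ndarray  # (n_taxa, n_sites) of '<U1'
    alphabet: Alphabet = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype="<U1")
        if self.data.ndim != 2:
            raise AlignmentFormatError("alignment data must be 2-D")
        if len(self.taxa) != self.data.shape[0]:
            raise AlignmentFormatError("taxa count does not match row count")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentFormatError(f"duplicate taxon name(s): {dupes}")
        if self.alphabet is None:
            self.alphabet = guess_alphabet(np.unique(self.data))
        for sym in np.unique(self.data):
            if not self.alphabet.is_valid(sym):
                raise AlignmentFormatError(
                    f"symbol {sym!r} not valid in {self.alphabet.name} alphabet")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequence(self, taxon: str) -> str:
        return "".join(self.data[self.taxa.index(taxon)])

    def subset_taxa(self, names) -> "Alignment":
        idx = [self.taxa.index(n) for n in names]
        return Alignment(list(names), self.data[idx], self.alphabet)

    def subset_sites(self, site_indices) -> "Alignment":
        return Alignment(list(self.taxa), self.data[:, site_indices], self.alphabet)

    def concat(self, other: "Alignment") -> "Alignment":
        if self.taxa != other.taxa:
            raise ValueError("taxon sets/orders differ")
        return Alignment(list(self.taxa),
                         np.concatenate([self.data, other.data], axis=1),
                         self.alphabet)

    def empirical_frequencies(self) -> np.ndarray:
        """State frequencies from unambiguous characters (pseudo-count free)."""
        counts = np.zeros(self.alphabet.size)
        for i, s in enumerate(self.alphabet.states):
            counts[i] = np.count_nonzero(self.data == s)
        total = counts.sum()
        if total == 0:
            return np.full(self.alphabet.size, 1.0 / self.alphabet.size)
        return counts / total

    def bootstrap(self, rng: np.random.Generator) -> "Alignment":
        """Nonparametric site bootstrap: resample columns with replacement."""
        idx = rng.integers(0, self.n_sites, size=self.n_sites)
        return self.subset_sites(idx)


@dataclass
class PatternAlignment:
    """Distinct site columns with multiplicities.

    Invariant: ``weights.sum() == original site count`` and expanding
    ``patterns[site_to_pattern]`` reproduces the original columns.
    """

    taxa: list[str]
    patterns: np.ndarray          # (n_patterns, n_taxa) of '<U1'
    weights: np.ndarray           # float (integer-valued for real data)
    site_to_pattern: np.ndarray   # (n_sites,) int
    alphabet: Alphabet

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_sites(self) -> int:
        return self.site_to_pattern.shape[0]

    def expand(self) -> Alignment:
        return Alignment(list(self.taxa),
                         self.patterns[self.site_to_pattern].T, self.alphabet)

    def leaf_partials(self) -> dict[str, np.ndarray]:
        """Per-taxon (n_patterns, n_states) 0/1 compatibility matrices."""
        out = {}
        for row, taxon in enumerate(self.taxa):
            M = np.empty((self.n_patterns, self.alphabet.size))
            for p in range(self.n_patterns):
                M[p] = self.alphabet.partial_row(self.patterns[p, row])
            out[taxon] = M
        return out


def compress_patterns(aln: Alignment) -> PatternAlignment:
    cols = aln.data.T  # (n_sites, n_taxa)
    # view each column as a joined string for fast uniqueness
    joined = np.array(["".join(c) for c in cols])
    uniq, first_idx, inverse = np.unique(joined, return_index=True, return_inverse=True)
    weights = np.bincount(inverse).astype(float)
    patterns = cols[first_idx]
    return PatternAlignment(list(aln.taxa), patterns, weights, inverse, aln.alphabet)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.lstrip().startswith(">") else "phylip"
    raise AlignmentFormatError(f"empty alignment file: {path}")


def read_alignment(path, format: str = "auto", alphabet: Alphabet | None = None) -> Alignment:
    """Read a FASTA or relaxed (sequential) PHYLIP alignment.

    Lowercase input is upcased; '.' (match-first) characters are rejected.
    Ragged rows and duplicate taxon names raise ``AlignmentFormatError``
    naming the offending taxon.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _sniff_format(path)

    names: list[str] = []
    seqs: list[str] = []
    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq).upper())
        if not names:
            raise AlignmentFormatError(f"no sequences found in {path}")
    elif format == "phylip":
        try:
            msa = AlignIO.read(str(path), "phylip-relaxed")
        except ValueError as e:
            raise AlignmentFormatError(f"PHYLIP parse failure in {path}: {e}") from e
        for rec in msa:
            names.append(rec.id)
            seqs.append(str(rec.seq).upper())
    else:
        raise ValueError(f"unknown alignment format: {format!r}")

    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        expect = len(seqs[0])
        for n, s in zip(names, seqs):
            if len(s) != expect:
                raise AlignmentFormatError(
                    f"ragged alignment: taxon {n!r} has length {len(s)}, expected {expect}")
    for n, s in zip(names, seqs):
        if "." in s:
            raise AlignmentFormatError(
                f"'.' characters are not supported (taxon {n!r})")
    data = np.array([list(s) for s in seqs], dtype="<U1")
    return Alignment(names, data, alphabet)


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if format == "fasta":
            for i, name in enumerate(aln.taxa):
                fh.write(f">{name}\n")
                seq = "".join(aln.data[i])
                for j in range(0, len(seq), 80):
                    fh.write(seq[j:j + 80] + "\n")
        elif format == "phylip":
            fh.write(f"{aln.n_taxa} {aln.n_sites}\n")
            for i, name in enumerate(aln.taxa):
                fh.write(f"{name}  {''.join(aln.data[i])}\n")
        else:
            raise ValueError(f"unknown alignment format: {format!r}")
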