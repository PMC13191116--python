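"""NEXUS-like charset partition blocks.

Grammar (one statement per line, case-insensitive keyword)::

    charset <name> = <start>-<end>[\\3];

Ranges are 1-based inclusive, optionally with a codon stride. Internally
partitions are materialized as 0-based site-index arrays.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Partition", "PartitionScheme", "read_partitions"]

_CHARSET_RE = re.compile(
    r"^\s*charset\s+(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*(\\(\d+))?\s*;\s*$",
    re.IGNORECASE)


@dataclass
class Partition:
    name: str
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive
    stride: int = 1
    model: str | None = None

    def site_indices(self) -> np.ndarray:
        """0-based site indices covered by this partition."""
        return np.arange(self.start - 1, self.end, self.stride)


@dataclass
class PartitionScheme:
    partitions: list[Partition] = field(default_factory=list)

    def __post_init__(self):
        seen: set[int] = set()
        for p in self.partitions:
            if p.start < 1 or p.end < p.start:
                raise ValueError(f"bad range in charset {p.name!r}: {p.start}-{p.end}")
            idx = set(p.site_indices().tolist())
            if idx & seen:
                raise ValueError(f"charset {p.name!r} overlaps a previous partition")
            seen |= idx

    def __iter__(self):
        return iter(self.partitions)

    def __len__(self):
        return len(self.partitions)

    def validate_against(self, n_sites: int) -> None:
        for p in self.partitions:
            if p.end > n_sites:
                raise ValueError(
                    f"charset {p.name!r} ends at {p.end} but alignment has {n_sites} sites")


def read_partitions(path) -> PartitionScheme:
    """Parse charset statements; lines `charset NAME = A-B[\\k];`.

    A trailing ``, model`` annotation after the range is not part of the
    dialect; per-partition models are attached via ``Partition.model``
    by the caller.
    """
    parts = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.strip().startswith("#"):
            continue
        m = _CHARSET_RE.match(line)
        if m is None:
            if "charset" in line.lower():
                raise ValueError(f"malformed charset statement at line {lineno}: {line.strip()!r}")
            continue  # tolerate begin/end block furniture
        name, a, b, _, stride = m.groups()
        parts.append(Partition(name, int(a), int(b), int(stride) if stride else 1))
    if not parts:
        raise ValueError(f"no charset statements found in {path}")
    return PartitionScheme(parts)
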