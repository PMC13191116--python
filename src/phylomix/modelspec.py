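"""Model-string grammar.

Strings follow the familiar ML-phylogenetics convention::

    BASE[+F|+FO|+FQ][+I][+G<m>[{alpha}]][+R<m>]
    MIX{BASE,BASE,...}[+suffixes]

with BASE one of JC, K2P, HKY, GTR, UNREST, POISSON, LG, WAG, JTT,
``Q.<file>`` (reversible PAML matrix) or ``NONREV.<file>`` (full
off-diagonal rates). ``+G`` and ``+R`` conflict. A MIX wrapper shares
one rate distribution across its matrix classes.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["ClassSpec", "ModelSpec", "parse_model_string"]

KNOWN_BASES = ("JC", "K2P", "HKY", "GTR", "UNREST", "POISSON", "LG", "WAG", "JTT")
_FIXED_FREQ_BASES = {"JC", "K2P", "POISSON"}      # uniform by construction
_FILE_FREQ_BASES = {"LG", "WAG", "JTT"}           # matrix file carries freqs


class ModelStringError(ValueError):
    pass


@dataclass(frozen=True)
class ClassSpec:
    base: str
    matrix_path: str | None = None

    def __str__(self):
        if self.base == "QFILE":
            return f"Q.{self.matrix_path}"
        if self.base == "NONREVFILE":
            return f"NONREV.{self.matrix_path}"
        return self.base

    @property
    def nonreversible(self) -> bool:
        return self.base in ("UNREST", "NONREVFILE")


@dataclass(frozen=True)
class ModelSpec:
    classes: tuple[ClassSpec, ...]
    freq_option: str = "default"   # default | F | FO | FQ
    invariant: bool = False
    rate_kind: str | None = None   # None | gamma | freerate
    rate_categories: int = 1
    gamma_alpha: float | None = None  # fixed alpha when given in braces
    source: str = ""

    @property
    def is_mixture(self) -> bool:
        return len(self.classes) > 1

    @property
    def nonreversible(self) -> bool:
        return any(c.nonreversible for c in self.classes)

    def canonical(self) -> str:
        if self.is_mixture:
            core = "MIX{" + ",".join(str(c) for c in self.classes) + "}"
        else:
            core = str(self.classes[0])
        parts = [core]
        if self.freq_option != "default":
            parts.append(self.freq_option)
        if self.invariant:
            parts.append("I")
        if self.rate_kind == "gamma":
            g = f"G{self.rate_categories}"
            if self.gamma_alpha is not None:
                g += f"{{{self.gamma_alpha:g}}}"
            parts.append(g)
        elif self.rate_kind == "freerate":
            parts.append(f"R{self.rate_categories}")
        return "+".join(parts)

    def __str__(self):
        return self.canonical()


def _parse_base(token: str) -> ClassSpec:
    if token.startswith("Q."):
        return ClassSpec("QFILE", token[2:])
    if token.startswith("NONREV."):
        return ClassSpec("NONREVFILE", token[7:])
    up = token.upper()
    if up not in KNOWN_BASES:
        raise ModelStringError(
            f"unknown base model {token!r}; known: {', '.join(KNOWN_BASES)}, "
            f"Q.<file>, NONREV.<file>")
    return ClassSpec(up)


_GAMMA_RE = re.compile(r"^G(\d*)(?:\{([0-9.eE+-]+)\})?$")
_FREERATE_RE = re.compile(r"^R(\d+)$")


def parse_model_string(text: str) -> ModelSpec:
    text = text.strip()
    if not text:
        raise ModelStringError("empty model string")
    if text.upper().startswith("MIX"):
        m = re.match(r"^MIX\{([^{}]*)\}(.*)$", text, re.IGNORECASE)
        if m is None:
            raise ModelStringError(f"malformed MIX braces in {text!r}")
        inner, rest = m.groups()
        bases = [b.strip() for b in inner.split(",") if b.strip()]
        if not bases:
            raise ModelStringError("MIX{...} needs at least one class")
        classes = tuple(_parse_base(b) for b in bases)
        suffixes = [s for s in rest.split("+") if s]
    else:
        head, *suffixes = text.split("+")
        classes = (_parse_base(head.strip()),)

    freq_option = "default"
    invariant = False
    rate_kind: str | None = None
    m_cats = 1
    alpha = None
    for raw in suffixes:
        s = raw.strip()
        su = s.upper()
        if su in ("F", "FO", "FQ"):
            if freq_option != "default":
                raise ModelStringError(f"conflicting frequency options in {text!r}")
            freq_option = su
        elif su == "I":
            invariant = True
        elif su.startswith("G") and _GAMMA_RE.match("G" + s[1:]):
            if rate_kind is not None:
                raise ModelStringError(
                    f"conflicting rate-heterogeneity suffixes in {text!r}")
            gm = _GAMMA_RE.match("G" + s[1:])
            m_cats = int(gm.group(1)) if gm.group(1) else 4
            alpha = float(gm.group(2)) if gm.group(2) else None
            rate_kind = "gamma"
        elif _FREERATE_RE.match(su):
            if rate_kind is not None:
                raise ModelStringError(
                    f"conflicting rate-heterogeneity suffixes in {text!r}")
            m_cats = int(_FREERATE_RE.match(su).group(1))
            rate_kind = "freerate"
        else:
            raise ModelStringError(f"unknown suffix {raw!r} in {text!r} "
                                   f"(position {text.find(raw)})")
    if rate_kind == "freerate" and m_cats < 2:
        raise ModelStringError("free-rates needs at least 2 categories")
    if m_cats < 1:
        raise ModelStringError("rate categories must be >= 1")
    return ModelSpec(classes, freq_option, invariant, rate_kind, m_cats,
                     alpha, source=text)
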