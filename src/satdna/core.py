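"""Shared sequence types and nucleotide primitives.

Everything downstream (monomerization, consensus, variability, trees) works on
plain uppercase nucleotide strings over the IUPAC alphabet; :class:`SeqRecord`
attaches an id and an optional library/group label (e.g. the sex of the
individual a read came from).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SeqRecord",
    "reverse_complement",
    "iupac_match",
    "at_content",
    "IUPAC_SETS",
    "COMPLEMENT",
]

# IUPAC nucleotide codes -> the set of unambiguous bases each one stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_COMPLEMENT_TABLE = str.maketrans(COMPLEMENT)


@dataclass
class SeqRecord:
    """An identified nucleotide sequence with an optional library/group label.

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    seq : str
        Nucleotide sequence over ``{A, C, G, T, N}`` (IUPAC codes tolerated).
        Normalized to uppercase on construction.
    label : str, optional
        Library or group tag, e.g. ``"male"`` / ``"female"``.
    source : str, optional
        Free-text provenance (file, accession, simulation).
    """

    id: str
    seq: str
    label: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        bad = set(self.seq) - set(IUPAC_SETS)
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"record {self.id!r}: non-nucleotide character "
                f"{self.seq[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    """Reverse complement of ``seq``; IUPAC codes map to their complements.

    Raises
    ------
    ValueError
        Naming the offending character and position if ``seq`` contains a
        non-nucleotide character.
    """
    s = seq.upper()
    for i, c in enumerate(s):
        if c not in COMPLEMENT:
            raise ValueError(f"non-nucleotide character {seq[i]!r} at position {i}")
    return s.translate(_COMPLEMENT_TABLE)[::-1]


def iupac_match(pattern: str, window: str) -> bool:
    """True iff every pattern code's nucleotide set contains the window base.

    ``N`` matches anything.  Both arguments must have equal length; the window
    must be unambiguous except that an ``N`` in the window matches only an
    ``N``-compatible pattern position (the pattern set must contain all bases).
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs window {len(window)}"
        )
    p = pattern.upper()
    w = window.upper()
    for i, (pc, wc) in enumerate(zip(p, w)):
        pset = IUPAC_SETS.get(pc)
        if pset is None:
            raise ValueError(f"non-nucleotide character {pattern[i]!r} at position {i}")
        wset = IUPAC_SETS.get(wc)
        if wset is None:
            raise ValueError(f"non-nucleotide character {window[i]!r} at position {i}")
        if not wset <= pset:
            return False
    return True


@dataclass(frozen=True)
class Undefined:
    """Distinguished 'undefined' result (zero comparable positions)."""

    reason: str = ""

    def __bool__(self) -> bool:  # an undefined value is falsy but not 0
        return False


UNDEFINED = Undefined()


def at_content(seq: str) -> float | Undefined:
    """Fraction (#A + #T) / (#A + #C + #G + #T).

    Ambiguity codes are excluded from numerator and denominator.  A sequence
    with no unambiguous base yields :data:`UNDEFINED` rather than 0.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    denom = a + c + g + t
    if denom == 0:
        return Undefined("no unambiguous bases")
    return (a + t) / denom
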