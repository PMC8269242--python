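"""Degenerate-nucleotide arithmetic.

A degenerate PCR primer written in the IUPAC alphabet is shorthand for a
mixture of concrete oligonucleotides: each ambiguity code denotes a set of
bases, and the primer denotes the Cartesian product of those sets. Everything
downstream — mismatch counting against environmental fragments, degeneracy
budgets, minimal-mixture design — reduces to set arithmetic on these codes.

A "mismatch" between a degenerate primer and a concrete (A/C/G/T) fragment is
a position where the fragment base is outside the primer code's set. For
concrete fragments this per-position rule is exactly the minimum Hamming
distance over all expansions of the primer, which is what matters chemically:
at least one oligo in the synthesised mixture anneals with that many
mismatches.
"""

from __future__ import annotations

import itertools
from typing import Iterable

__all__ = [
    "IUPAC_SETS",
    "normalize",
    "iupac_set",
    "code_for_set",
    "degeneracy",
    "expand",
    "count_mismatches",
    "reverse_complement",
    "is_concrete",
]

#: IUPAC nucleotide codes -> the set of concrete bases each denotes.
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

_CODE_BY_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "S": "S", "W": "W", "N": "N",
}

#: Default ceiling on expansion size; the widest primer discussed in marine
#: SSU work expands to 144 oligos, so 4096 is a generous guard against typos.
DEFAULT_EXPANSION_CAP = 4096


class InvalidNucleotideError(ValueError):
    """A sequence contains a character outside the IUPAC alphabet."""

    def __init__(self, sequence: str, position: int):
        self.position = position
        self.offending = sequence[position]
        super().__init__(
            f"invalid nucleotide code {self.offending!r} at position "
            f"{position + 1} of {sequence!r}"
        )


def normalize(seq: str) -> str:
    """Uppercase a sequence, map U to T, and validate the IUPAC alphabet.

    Raises :class:`InvalidNucleotideError` naming the first bad position.
    """
    up = seq.upper().replace("U", "T")
    for i, c in enumerate(up):
        if c not in IUPAC_SETS:
            raise InvalidNucleotideError(up, i)
    return up


def iupac_set(code: str) -> frozenset[str]:
    """Set of concrete bases denoted by a single IUPAC code."""
    if len(code) != 1:
        raise ValueError(f"expected a single character, got {code!r}")
    c = normalize(code)
    return IUPAC_SETS[c]


def code_for_set(bases: Iterable[str]) -> str:
    """Minimal IUPAC code whose set equals the given nonempty base set."""
    key = frozenset(bases)
    try:
        return _CODE_BY_SET[key]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(key)}") from None


def degeneracy(seq: str) -> int:
    """Number of concrete oligos a degenerate sequence encodes.

    Product over positions of the IUPAC set sizes; equals ``len(expand(seq))``.
    """
    seq = normalize(seq)
    n = 1
    for c in seq:
        n *= len(IUPAC_SETS[c])
    return n


def expand(seq: str, cap: int = DEFAULT_EXPANSION_CAP) -> list[str]:
    """All concrete sequences compatible with ``seq``, lexicographically sorted.

    Refuses (``ValueError``) when the expansion would exceed ``cap``.
    """
    seq = normalize(seq)
    count = degeneracy(seq)
    if count > cap:
        raise ValueError(
            f"expansion of {seq!r} has {count} oligos, exceeding the cap of "
            f"{cap}; raise the cap explicitly if this is intended"
        )
    choices = [sorted(IUPAC_SETS[c]) for c in seq]
    return ["".join(p) for p in itertools.product(*choices)]


def is_concrete(seq: str) -> bool:
    """True if the (normalized) sequence contains only A/C/G/T."""
    return all(c in "ACGT" for c in seq.upper().replace("U", "T"))


def count_mismatches(primer_seq: str, fragment: str) -> int:
    """Mismatches between a degenerate primer and a concrete fragment.

    Counts positions where the fragment base falls outside the primer code's
    set; 0 means the fragment is perfectly matched by at least one oligo of
    the primer mixture. Fragments must be concrete — ambiguous read bases are
    excluded upstream rather than scored.
    """
    p = normalize(primer_seq)
    f = normalize(fragment)
    if len(p) != len(f):
        raise ValueError(
            f"length mismatch: primer has {len(p)} bases, fragment {len(f)}"
        )
    if not is_concrete(f):
        bad = next(i for i, c in enumerate(f) if c not in "ACGT")
        raise ValueError(
            f"fragment contains ambiguity code {f[bad]!r} at position "
            f"{bad + 1}; ambiguous fragments are excluded, not scored"
        )
    return sum(fb not in IUPAC_SETS[pc] for pc, fb in zip(p, f))


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC codes mapped set-wise (Y<->R, M<->K...).

    Involutive: ``reverse_complement(reverse_complement(s)) == s``.
    """
    seq = normalize(seq)
    return "".join(_COMPLEMENT[c] for c in reversed(seq))
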