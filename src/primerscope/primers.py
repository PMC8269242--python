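"""Primer definitions: the DegeneratePrimer record, oligo sets, and loading.

Primer coordinates follow the field convention of positions on the
E. coli K-12 MG1655 16S rRNA gene (1-based, inclusive), or on whichever
group-specific reference the configuration names. A primer's ``sequence`` is
written 5'->3' as the oligo is synthesised; a reverse primer therefore
anneals to the plus strand of the reference as the reverse complement of its
written sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from . import iupac

GROUPS = ("Archaea", "Bacteria", "Cyanobacteria_plastid", "Eukarya")


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named degenerate primer with orientation and reference coordinates."""

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"
    reference: str = "Ecoli_16S"
    ref_start: int = 1
    ref_end: int = 0
    targeted_groups: tuple[str, ...] = GROUPS

    def __post_init__(self):
        object.__setattr__(self, "sequence", iupac.normalize(self.sequence))
        if not self.sequence:
            raise ValueError(f"primer {self.name!r}: empty sequence")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(
                f"primer {self.name!r}: orientation must be 'forward' or "
                f"'reverse', got {self.orientation!r}"
            )
        if self.ref_end == 0:
            object.__setattr__(
                self, "ref_end", self.ref_start + len(self.sequence) - 1
            )
        if self.ref_end - self.ref_start + 1 != len(self.sequence):
            raise ValueError(
                f"primer {self.name!r}: coordinates {self.ref_start}.."
                f"{self.ref_end} span {self.ref_end - self.ref_start + 1} "
                f"bases but the sequence has {len(self.sequence)}"
            )
        bad = set(self.targeted_groups) - set(GROUPS)
        if bad:
            raise ValueError(
                f"primer {self.name!r}: unknown groups {sorted(bad)}; "
                f"expected a subset of {GROUPS}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        return iupac.degeneracy(self.sequence)

    @property
    def binding_pattern(self) -> str:
        """The pattern the primer site shows on the reference plus strand.

        Fragments are extracted in reference orientation, so reverse primers
        are compared as the reverse complement of their written sequence.
        """
        if self.orientation == "reverse":
            return iupac.reverse_complement(self.sequence)
        return self.sequence

    def expand(self, cap: int = iupac.DEFAULT_EXPANSION_CAP) -> "OligoSet":
        return OligoSet(self.name, iupac.expand(self.sequence, cap=cap))


@dataclass(frozen=True)
class OligoSet:
    """An ordered, deduplicated set of concrete equal-length oligos."""

    primer_name: str
    oligos: tuple[str, ...] = ()

    def __init__(self, primer_name: str, oligos: Iterable[str]):
        object.__setattr__(self, "primer_name", primer_name)
        seen: dict[str, None] = {}
        for o in oligos:
            o = iupac.normalize(o)
            if not iupac.is_concrete(o):
                raise ValueError(
                    f"oligo {o!r} in set {primer_name!r} is not concrete"
                )
            seen.setdefault(o)
        oligos_t = tuple(seen)
        if oligos_t and len({len(o) for o in oligos_t}) > 1:
            raise ValueError(
                f"oligos in set {primer_name!r} have unequal lengths"
            )
        object.__setattr__(self, "oligos", oligos_t)

    def __len__(self) -> int:
        return len(self.oligos)

    def __iter__(self):
        return iter(self.oligos)

    def __contains__(self, oligo: str) -> bool:
        return oligo in self.oligos


# Primers in broad use for marine SSU rRNA surveys, with E. coli 16S
# coordinates. 806RB lacks an 18S binding site, hence no Eukarya target;
# 341F/785R were designed for prokaryotes.
BUILTIN_PRIMERS: dict[str, DegeneratePrimer] = {
    p.name: p
    for p in (
        DegeneratePrimer(
            "515Y", "GTGYCAGCMGCCGCGGTAA", "forward",
            ref_start=515, ref_end=533,
        ),
        DegeneratePrimer(
            "926R", "CCGYCAATTYMTTTRAGTTT", "reverse",
            ref_start=906, ref_end=925,
        ),
        DegeneratePrimer(
            "806RB", "GGACTACNVGGGTWTCTAAT", "reverse",
            ref_start=787, ref_end=806,
            targeted_groups=("Archaea", "Bacteria", "Cyanobacteria_plastid"),
        ),
        DegeneratePrimer(
            "785R", "GACTACHVGGGTATCTAATCC", "reverse",
            ref_start=785, ref_end=805,
            targeted_groups=("Archaea", "Bacteria", "Cyanobacteria_plastid"),
        ),
        DegeneratePrimer(
            "341F", "CCTACGGGNGGCWGCAG", "forward",
            ref_start=341, ref_end=357,
            targeted_groups=("Archaea", "Bacteria", "Cyanobacteria_plastid"),
        ),
    )
}


def get_primer(name: str) -> DegeneratePrimer:
    """Look up a built-in primer by name."""
    try:
        return BUILTIN_PRIMERS[name]
    except KeyError:
        raise KeyError(
            f"unknown primer {name!r}; built-ins are "
            f"{sorted(BUILTIN_PRIMERS)}"
        ) from None


def load_primers(path: str | Path) -> dict[str, DegeneratePrimer]:
    """Load primer definitions from a YAML file.

    Expected layout::

        primers:
          - name: 515Y
            sequence: GTGYCAGCMGCCGCGGTAA
            orientation: forward
            reference: Ecoli_16S
            ref_start: 515
            ref_end: 533
            targeted_groups: [Archaea, Bacteria, Cyanobacteria_plastid, Eukarya]

    ``ref_end`` and ``targeted_groups`` are optional (derived from the
    sequence length / defaulting to all four categories).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "primers" not in doc:
        raise ValueError(f"{path}: expected a top-level 'primers' list")
    out: dict[str, DegeneratePrimer] = {}
    for entry in doc["primers"]:
        try:
            primer = DegeneratePrimer(
                name=entry["name"],
                sequence=entry["sequence"],
                orientation=entry["orientation"],
                reference=entry.get("reference", "Ecoli_16S"),
                ref_start=int(entry.get("ref_start", 1)),
                ref_end=int(entry.get("ref_end", 0)),
                targeted_groups=tuple(entry.get("targeted_groups", GROUPS)),
            )
        except KeyError as e:
            raise ValueError(
                f"{path}: primer entry {entry!r} is missing key {e}"
            ) from None
        out[primer.name] = primer
    return out
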