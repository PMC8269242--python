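"""Extract primer-binding-region fragments from aligned reads.

Reads aligned to a group-specific SSU rRNA reference carry, when they span a
primer's coordinates, the exact environmental sequence of that primer site.
This module cuts those windows out of SAM alignments, applies the spanning
rule (full primer window plus a flank on at least one side), quality-filters,
drops ambiguous fragments, and discards gross mismatches that indicate
misalignment rather than genuine primer-site variation.

The filter chain and its order are fixed and tallied so that input reads are
conserved: every SAM record is accounted for exactly once across the tally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional

import pysam

from . import iupac
from .primers import GROUPS, DegeneratePrimer

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 5
DEFAULT_MIN_MEAN_QUALITY = 30.0
DEFAULT_EXCLUSION_MISMATCHES = 6


@dataclass(frozen=True)
class PrimerRegionFragment:
    """One read's subsequence over a primer window, in reference orientation."""

    read_id: str
    sample_id: str
    group: str
    primer_name: str
    bases: str
    mean_quality: Optional[float] = None  # absent for FASTA input
    flank_sides: str = ""  # which sides met the flank requirement: L, R, LR
    n_mismatches: Optional[int] = None  # filled in by the scoring step


@dataclass
class ExtractionTally:
    """Per-stage read accounting; input = extracted + sum of removals."""

    n_records: int = 0
    n_unmapped: int = 0
    n_secondary_supplementary: int = 0
    n_wrong_reference: int = 0
    n_not_spanning: int = 0
    n_indel_in_window: int = 0
    n_unlabeled: int = 0
    n_extracted: int = 0
    n_quality_removed: int = 0
    n_ambiguous_removed: int = 0
    n_excluded_mismatch: int = 0
    n_retained: int = 0

    def conserved(self) -> bool:
        removed_pre = (
            self.n_unmapped
            + self.n_secondary_supplementary
            + self.n_wrong_reference
            + self.n_not_spanning
            + self.n_indel_in_window
            + self.n_unlabeled
        )
        post = (
            self.n_retained
            + self.n_quality_removed
            + self.n_ambiguous_removed
            + self.n_excluded_mismatch
        )
        return (
            self.n_records == removed_pre + self.n_extracted
            and self.n_extracted == post
        )


def extract_fragments(
    sam_path: str | Path,
    primer: DegeneratePrimer,
    sample_id: str,
    group_of: Mapping[str, str] | None = None,
    default_group: str | None = None,
    flank: int = DEFAULT_FLANK,
    require_both_flanks: bool = False,
    tally: ExtractionTally | None = None,
) -> list[PrimerRegionFragment]:
    """Extract one fragment per spanning alignment over the primer window.

    Parameters
    ----------
    sam_path
        Headered SAM with a single reference matching ``primer.reference``.
    group_of
        read_id -> organismal category (sidecar labels). Alternatively pass
        ``default_group`` when the whole file is one category.
    flank
        Required reference flank beyond the window (default 5 bases).
    require_both_flanks
        If True the alignment must cover the window plus ``flank`` bases on
        both sides; by default one side suffices (recorded per fragment).

    Spanning rule: the alignment must cover every reference column of the
    primer window with aligned (non-indel) read bases, and additionally reach
    ``flank`` reference bases beyond the window on at least one side (both
    sides with ``require_both_flanks``). Reads with insertions or deletions
    inside the window are skipped: a length-changing variant cannot be scored
    by positional mismatch counting.
    """
    if group_of is None and default_group is None:
        raise ValueError("provide group_of labels or a default_group")
    if default_group is not None and default_group not in GROUPS:
        raise ValueError(f"unknown group {default_group!r}")
    t = tally if tally is not None else ExtractionTally()
    win_start = primer.ref_start - 1  # 0-based half-open window
    win_end = primer.ref_end
    fragments: list[PrimerRegionFragment] = []

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=True) as sam:
        refs = list(sam.references)
        if primer.reference not in refs:
            raise ValueError(
                f"{sam_path}: reference {primer.reference!r} absent from "
                f"header (found {refs})"
            )
        ref_len = sam.get_reference_length(primer.reference)
        if not (0 <= win_start < win_end <= ref_len):
            raise ValueError(
                f"primer {primer.name!r} window {primer.ref_start}.."
                f"{primer.ref_end} out of range for reference "
                f"{primer.reference!r} of length {ref_len}"
            )
        for rec in sam.fetch(until_eof=True):
            t.n_records += 1
            if rec.is_unmapped:
                t.n_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                t.n_secondary_supplementary += 1
                continue
            if rec.reference_name != primer.reference:
                t.n_wrong_reference += 1
                continue
            span_start, span_end = rec.reference_start, rec.reference_end
            left_ok = span_start <= win_start - flank
            right_ok = span_end >= win_end + flank
            covers = span_start <= win_start and span_end >= win_end
            flank_ok = (left_ok and right_ok) if require_both_flanks \
                else (left_ok or right_ok)
            if not (covers and flank_ok):
                t.n_not_spanning += 1
                continue
            window = _window_bases(rec, win_start, win_end)
            if window is None:
                t.n_indel_in_window += 1
                continue
            bases, quals = window
            if group_of is not None:
                group = group_of.get(rec.query_name, default_group)
                if group is None:
                    t.n_unlabeled += 1
                    continue
            else:
                group = default_group
            mean_q = (
                sum(quals) / len(quals) if quals is not None else None
            )
            sides = ("L" if left_ok else "") + ("R" if right_ok else "")
            fragments.append(
                PrimerRegionFragment(
                    read_id=rec.query_name,
                    sample_id=sample_id,
                    group=group,
                    primer_name=primer.name,
                    bases=bases.upper().replace("U", "T"),
                    mean_quality=mean_q,
                    flank_sides=sides,
                )
            )
            t.n_extracted += 1
    return fragments


def _window_bases(rec, win_start: int, win_end: int):
    """Read bases aligned to reference columns [win_start, win_end).

    Returns None when any window column lacks an aligned base or the aligned
    query positions are non-contiguous (insertion inside the window).
    """
    qpos_by_ref = {
        r: q
        for q, r in rec.get_aligned_pairs(matches_only=True)
        if win_start <= r < win_end
    }
    if len(qpos_by_ref) != win_end - win_start:
        return None  # deletion: some window column has no read base
    qpos = [qpos_by_ref[r] for r in range(win_start, win_end)]
    if qpos != list(range(qpos[0], qpos[0] + len(qpos))):
        return None  # insertion inside the window
    seq = rec.query_sequence[qpos[0]: qpos[-1] + 1]
    quals = rec.query_qualities
    q = list(quals[qpos[0]: qpos[-1] + 1]) if quals is not None else None
    return seq, q


def quality_filter(
    fragments: Iterable[PrimerRegionFragment],
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
    tally: ExtractionTally | None = None,
) -> list[PrimerRegionFragment]:
    """Drop fragments whose mean Phred quality over the window is below cutoff.

    Fragments without quality (FASTA input) pass through with a logged notice.
    """
    kept: list[PrimerRegionFragment] = []
    n_removed = n_noq = 0
    for f in fragments:
        if f.mean_quality is None:
            n_noq += 1
            kept.append(f)
        elif f.mean_quality >= min_mean_quality:
            kept.append(f)
        else:
            n_removed += 1
    if n_noq:
        logger.info(
            "quality_filter: %d fragments had no quality values and were "
            "passed through", n_noq,
        )
    if tally is not None:
        tally.n_quality_removed += n_removed
    logger.info("quality_filter: removed %d fragments below Q%.1f",
                n_removed, min_mean_quality)
    return kept


def drop_ambiguous(
    fragments: Iterable[PrimerRegionFragment],
    tally: ExtractionTally | None = None,
) -> list[PrimerRegionFragment]:
    """Drop fragments containing any non-A/C/G/T character (including N).

    Ambiguous read bases are uninformative for matching; excluding them
    inflates neither the matched nor the mismatched tally.
    """
    fragments = list(fragments)
    kept = [f for f in fragments if iupac.is_concrete(f.bases)]
    n_removed = len(fragments) - len(kept)
    if tally is not None:
        tally.n_ambiguous_removed += n_removed
    return kept


def score_fragments(
    fragments: Iterable[PrimerRegionFragment],
    primer: DegeneratePrimer,
) -> list[PrimerRegionFragment]:
    """Annotate each fragment with its mismatch count to the primer.

    Fragments are in reference orientation, so the comparison pattern is the
    primer's plus-strand binding pattern (reverse complement for reverse
    primers).
    """
    pattern = primer.binding_pattern
    return [
        replace(f, n_mismatches=iupac.count_mismatches(pattern, f.bases))
        for f in fragments
    ]


def exclusion_filter(
    fragments: Iterable[PrimerRegionFragment],
    primer: DegeneratePrimer,
    max_mm: int = DEFAULT_EXCLUSION_MISMATCHES,
    tally: ExtractionTally | None = None,
) -> list[PrimerRegionFragment]:
    """Drop fragments with more than ``max_mm`` mismatches to the primer.

    Such reads are treated as misalignments or distantly related sequences
    rather than genuine primer-site variants; the boundary is inclusive
    (exactly ``max_mm`` mismatches is retained).
    """
    scored = [
        f if f.n_mismatches is not None else
        replace(f, n_mismatches=iupac.count_mismatches(
            primer.binding_pattern, f.bases))
        for f in fragments
    ]
    kept = [f for f in scored if f.n_mismatches <= max_mm]
    n_removed = len(scored) - len(kept)
    if tally is not None:
        tally.n_excluded_mismatch += n_removed
    logger.info(
        "exclusion_filter(%s): removed %d fragments with >%d mismatches",
        primer.name, n_removed, max_mm,
    )
    return kept


def run_extraction(
    sam_path: str | Path,
    primer: DegeneratePrimer,
    sample_id: str,
    group_of: Mapping[str, str] | None = None,
    default_group: str | None = None,
    flank: int = DEFAULT_FLANK,
    require_both_flanks: bool = False,
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
    max_mm: int = DEFAULT_EXCLUSION_MISMATCHES,
) -> tuple[list[PrimerRegionFragment], ExtractionTally]:
    """Full fragment pipeline: extract -> quality -> drop non-ACGT -> exclude.

    Returns scored, filtered fragments plus the read-conservation tally.
    """
    tally = ExtractionTally()
    frags = extract_fragments(
        sam_path, primer, sample_id,
        group_of=group_of, default_group=default_group,
        flank=flank, require_both_flanks=require_both_flanks, tally=tally,
    )
    frags = quality_filter(frags, min_mean_quality, tally=tally)
    frags = drop_ambiguous(frags, tally=tally)
    frags = score_fragments(frags, primer)
    frags = exclusion_filter(frags, primer, max_mm=max_mm, tally=tally)
    tally.n_retained = len(frags)
    assert tally.conserved(), "read conservation violated"
    return frags, tally


def load_fragments(
    path: str | Path,
    primer: DegeneratePrimer,
    sample_id: str,
    group_of: Mapping[str, str] | None = None,
    default_group: str | None = None,
    fmt: str | None = None,
) -> list[PrimerRegionFragment]:
    """Load pre-extracted primer-region fragments from FASTA or FASTQ.

    Sequences must already be exactly the primer window in reference
    orientation; records whose length differs from the primer are rejected.
    FASTA records carry no quality (``mean_quality`` is None and the quality
    filter passes them through with a notice). Groups come from ``group_of``
    (e.g. :func:`load_group_labels`) or ``default_group``.
    """
    from Bio import SeqIO

    if group_of is None and default_group is None:
        raise ValueError("provide group_of labels or a default_group")
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    frags: list[PrimerRegionFragment] = []
    for rec in SeqIO.parse(str(path), fmt):
        seq = str(rec.seq).upper().replace("U", "T")
        if len(seq) != len(primer):
            raise ValueError(
                f"{path}: record {rec.id!r} has length {len(seq)}, expected "
                f"the primer window length {len(primer)}"
            )
        group = (group_of or {}).get(rec.id, default_group)
        if group is None:
            raise ValueError(f"{path}: record {rec.id!r} has no group label")
        quals = rec.letter_annotations.get("phred_quality")
        frags.append(
            PrimerRegionFragment(
                read_id=rec.id,
                sample_id=sample_id,
                group=group,
                primer_name=primer.name,
                bases=seq,
                mean_quality=(sum(quals) / len(quals)) if quals else None,
            )
        )
    return frags


def write_fragments_fasta(
    fragments: Iterable[PrimerRegionFragment], path: str | Path
) -> None:
    """Write fragments as FASTA (reference orientation, window bases only)."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f">{f.read_id}\n{f.bases}\n")


def load_group_labels(path: str | Path) -> dict[str, str]:
    """Read a sidecar TSV of ``read_id<TAB>group`` (no header, '#' comments)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            read_id, group = line.split("\t")[:2]
            if group not in GROUPS:
                raise ValueError(
                    f"{path}: unknown group {group!r} for read {read_id!r}"
                )
            labels[read_id] = group
    return labels
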