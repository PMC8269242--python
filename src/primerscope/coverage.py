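"""Primer coverage statistics over scored fragments.

Coverage of a primer in a sample x organismal-group cell is the fraction of
primer-region fragments matched at a given mismatch threshold; the 0-mismatch
("perfect match") fraction is the headline metric, since even one primer-
template mismatch can bias amplification severalfold. Pair statistics combine
a forward and a reverse primer over the groups both are expected to bind
(the taxonomic-overlap correction), under three explicit rules:

* ``product`` — independence assumption, cov_f * cov_r. The two primer
  regions are observed on different short reads, so per-molecule linkage is
  unavailable; independence is the neutral default.
* ``min`` — the better-matched primer never rescues the worse one.
* ``worst_case`` — lower bound 1 - (missed_f + missed_r), i.e. the missed
  organism sets are assumed disjoint; clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .extract import PrimerRegionFragment
from .primers import DegeneratePrimer

DEFAULT_THRESHOLDS = (0, 1, 2)
PAIR_RULES = ("product", "min", "worst_case")


@dataclass(frozen=True)
class CoverageRecord:
    """Match fractions for one sample x group x primer cell."""

    sample_id: str
    group: str
    primer_name: str
    n_total: int
    n_match: dict  # threshold -> cumulative count at <= threshold mismatches
    coverage: dict  # threshold -> fraction, or None when n_total == 0

    def coverage_at(self, k: int) -> Optional[float]:
        return self.coverage[k]


def coverage_records(
    fragments: Iterable[PrimerRegionFragment],
    primer: DegeneratePrimer,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    expected_cells: Optional[Sequence[tuple[str, str]]] = None,
) -> list[CoverageRecord]:
    """Count matches per sample x group at each cumulative mismatch threshold.

    ``expected_cells`` lists (sample_id, group) cells that must appear in the
    output even without fragments; such cells report coverage ``None``
    (absence of evidence is not zero coverage), never 0/0. Fragments must
    already be scored (``n_mismatches``).
    """
    cells: dict[tuple[str, str], list[int]] = {
        tuple(c): [] for c in (expected_cells or [])
    }
    for f in fragments:
        if f.primer_name != primer.name:
            continue
        if f.n_mismatches is None:
            raise ValueError(
                f"fragment {f.read_id!r} is unscored; run score_fragments"
            )
        cells.setdefault((f.sample_id, f.group), []).append(f.n_mismatches)
    records = []
    for (sample_id, group), mms in sorted(cells.items()):
        n_total = len(mms)
        n_match = {k: sum(1 for m in mms if m <= k) for k in thresholds}
        cov = {
            k: (n_match[k] / n_total if n_total else None) for k in thresholds
        }
        records.append(
            CoverageRecord(sample_id, group, primer.name, n_total, n_match, cov)
        )
    return records


def coverage_table(
    fragments: Iterable[PrimerRegionFragment],
    primer: DegeneratePrimer,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    expected_cells: Optional[Sequence[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Tidy coverage table: one row per sample x group."""
    rows = []
    for r in coverage_records(fragments, primer, thresholds, expected_cells):
        row = {
            "sample_id": r.sample_id,
            "group": r.group,
            "primer": r.primer_name,
            "n_total": r.n_total,
        }
        for k in thresholds:
            row[f"n_match_{k}mm"] = r.n_match[k]
            row[f"coverage_{k}mm"] = (
                np.nan if r.coverage[k] is None else r.coverage[k]
            )
        rows.append(row)
    cols = ["sample_id", "group", "primer", "n_total"] + [
        c for k in thresholds for c in (f"n_match_{k}mm", f"coverage_{k}mm")
    ]
    return pd.DataFrame(rows, columns=cols)


def worst_case_pair(coverage_fwd: float, coverage_rev: float) -> float:
    """Lower bound on combined pair coverage: 1 - (missed_fwd + missed_rev).

    Assumes the organisms missed by the two primers are disjoint sets;
    clamped at zero.
    """
    for name, c in (("forward", coverage_fwd), ("reverse", coverage_rev)):
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"{name} coverage {c} outside [0, 1]")
    return max(0.0, 1.0 - ((1.0 - coverage_fwd) + (1.0 - coverage_rev)))


def pair_coverage(
    fwd_table: pd.DataFrame,
    rev_table: pd.DataFrame,
    fwd_primer: DegeneratePrimer,
    rev_primer: DegeneratePrimer,
    rule: str = "product",
) -> pd.DataFrame:
    """Combine per-primer 0-mm coverage into pair coverage per sample x group.

    Only groups targeted by BOTH primers are reported — the taxonomic-overlap
    correction (e.g. a pair whose reverse primer lacks an 18S binding site
    reports no Eukarya row even if the forward primer covers Eukarya).
    All three combination rules are emitted; ``rule`` selects which one is
    copied into the ``pair_coverage`` column.
    """
    if rule not in PAIR_RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {PAIR_RULES}")
    shared = [
        g for g in fwd_primer.targeted_groups
        if g in rev_primer.targeted_groups
    ]
    if not shared:
        import warnings

        warnings.warn(
            f"primers {fwd_primer.name}/{rev_primer.name} share no targeted "
            "groups; empty pair table", stacklevel=2,
        )
        return pd.DataFrame(
            columns=[
                "sample_id", "group", "fwd_primer", "rev_primer",
                "coverage_fwd", "coverage_rev", "product", "min",
                "worst_case", "pair_coverage", "rule",
            ]
        )
    f = fwd_table[fwd_table["group"].isin(shared)]
    r = rev_table[rev_table["group"].isin(shared)]
    merged = f.merge(
        r, on=["sample_id", "group"], suffixes=("_fwd", "_rev"), how="inner"
    )
    out = pd.DataFrame(
        {
            "sample_id": merged["sample_id"],
            "group": merged["group"],
            "fwd_primer": fwd_primer.name,
            "rev_primer": rev_primer.name,
            "coverage_fwd": merged["coverage_0mm_fwd"],
            "coverage_rev": merged["coverage_0mm_rev"],
        }
    )
    out["product"] = out["coverage_fwd"] * out["coverage_rev"]
    out["min"] = out[["coverage_fwd", "coverage_rev"]].min(axis=1)
    out["worst_case"] = np.maximum(
        0.0, 1.0 - ((1.0 - out["coverage_fwd"]) + (1.0 - out["coverage_rev"]))
    )
    out["pair_coverage"] = out[rule]
    out["rule"] = rule
    return out


def summarize_across_samples(
    table: pd.DataFrame,
    value_col: str = "coverage_0mm",
    by: Sequence[str] = ("primer", "group"),
) -> pd.DataFrame:
    """Median, quartiles and range of a coverage column across samples."""
    if table.empty:
        raise ValueError("no records to summarize")
    g = table.groupby(list(by))[value_col]
    out = g.agg(
        n_samples="count",
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
        min="min",
        max="max",
    ).reset_index()
    return out
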