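"""Primer-site variant tables and minimal oligonucleotide mixture design.

Instead of widening a primer with IUPAC degeneracies — which multiplies the
synthesised mixture by the product of the new set sizes and dilutes the
perfectly matching oligos with variants never seen in nature — a minimal
mixture starts from a concrete seed oligo and adds only the primer-site
variants actually observed in environmental data above an abundance
threshold, plus any curated additions (e.g. organellar variants known from
reference databases). The table of observed variants, their per-dataset
frequencies, and their mismatch counts to the current primer is the raw
material for both that design and for ranked single-degeneracy fixes to an
existing primer.

Variant sequences are reported in primer (synthesis) orientation: fragments
from reverse primers are reverse-complemented so each row reads as an oligo
one could order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import iupac
from .extract import PrimerRegionFragment
from .primers import DegeneratePrimer, OligoSet

DEFAULT_ABUNDANCE_THRESHOLD = 0.02
DEFAULT_MIN_COUNT = 2


def tabulate_variants(
    fragments: Iterable[PrimerRegionFragment],
    primer: DegeneratePrimer,
    dataset_of: Optional[dict] = None,
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.DataFrame:
    """Tabulate distinct primer-site sequences with per-dataset frequencies.

    Datasets default to ``sample_id`` (pass ``dataset_of`` mapping sample_id
    -> dataset to pool samples). Rows are sorted by overall relative
    abundance (unweighted mean of per-dataset relative abundances, each
    dataset counting equally) descending, ties broken lexicographically.

    Columns: ``variant``, ``n_mismatches``, ``matched`` (0 mm to the primer),
    ``count_<ds>`` and ``freq_<ds>`` per dataset, ``total_count``,
    ``overall_abundance``, and ``possible_error`` flagging variants whose
    count in every dataset is below ``min_count`` (the long tail that may
    derive from sequencing error; flagged, never dropped from the table).
    """
    counts: dict[str, dict[str, int]] = {}
    for f in fragments:
        if f.primer_name != primer.name:
            continue
        ds = dataset_of.get(f.sample_id, f.sample_id) if dataset_of \
            else f.sample_id
        variant = (
            iupac.reverse_complement(f.bases)
            if primer.orientation == "reverse" else f.bases
        )
        counts.setdefault(variant, {})
        counts[variant][ds] = counts[variant].get(ds, 0) + 1
    if not counts:
        return pd.DataFrame(
            columns=["variant", "n_mismatches", "matched", "total_count",
                     "overall_abundance", "possible_error"]
        )
    datasets = sorted({ds for per in counts.values() for ds in per})
    df = pd.DataFrame(
        {
            "variant": list(counts),
            **{
                f"count_{ds}": [counts[v].get(ds, 0) for v in counts]
                for ds in datasets
            },
        }
    )
    totals = {ds: df[f"count_{ds}"].sum() for ds in datasets}
    for ds in datasets:
        df[f"freq_{ds}"] = df[f"count_{ds}"] / totals[ds] if totals[ds] else 0.0
    df["total_count"] = df[[f"count_{ds}" for ds in datasets]].sum(axis=1)
    df["overall_abundance"] = df[[f"freq_{ds}" for ds in datasets]].mean(axis=1)
    df["n_mismatches"] = [
        iupac.count_mismatches(primer.sequence, v) for v in df["variant"]
    ]
    df["matched"] = df["n_mismatches"] == 0
    df["possible_error"] = (
        df[[f"count_{ds}" for ds in datasets]].lt(min_count).all(axis=1)
    )
    df = df.sort_values(
        ["overall_abundance", "variant"], ascending=[False, True]
    ).reset_index(drop=True)
    front = ["variant", "n_mismatches", "matched", "total_count",
             "overall_abundance", "possible_error"]
    return df[front + [c for c in df.columns if c not in front]]


def _dataset_names(table: pd.DataFrame) -> list[str]:
    return [c[len("freq_"):] for c in table.columns if c.startswith("freq_")]


def degenerate_union(oligos: Sequence[str]) -> str:
    """Minimal single IUPAC sequence whose expansion covers all oligos."""
    if not oligos:
        raise ValueError("empty oligo collection")
    oligos = [iupac.normalize(o) for o in oligos]
    if len({len(o) for o in oligos}) != 1:
        raise ValueError("oligos have unequal lengths")
    return "".join(
        iupac.code_for_set({o[i] for o in oligos})
        for i in range(len(oligos[0]))
    )


@dataclass(frozen=True)
class MixtureDesign:
    """An explicit oligo mixture with its provenance and achieved coverage."""

    primer_name: str
    seed: str
    oligos: OligoSet
    justification: dict  # oligo -> "seed" | "observed>threshold" | "curated"
    achieved_coverage: dict  # dataset -> summed abundance of matched variants
    overall_coverage: float
    degenerate_union: str
    union_degeneracy: int
    abundance_threshold: float

    @property
    def n_oligos(self) -> int:
        return len(self.oligos)


def design_mixture(
    table: pd.DataFrame,
    primer_name: str,
    seed: Optional[str] = None,
    abundance_threshold: float = DEFAULT_ABUNDANCE_THRESHOLD,
    must_include: Sequence[str] = (),
    exclude_possible_errors: bool = False,
) -> MixtureDesign:
    """Design a minimal explicit mixture from an observed variant table.

    The mixture is {seed} ∪ {variants with overall relative abundance
    strictly above ``abundance_threshold``} ∪ ``must_include`` (curated
    additions such as database-derived organellar variants), deduplicated.
    ``seed`` defaults to the highest-abundance variant matched by the
    original primer (falling back to the top variant if none is matched).

    Achieved coverage per dataset is recomputed from the table: the summed
    relative abundance of variants equal to some mixture member. Setting
    ``exclude_possible_errors`` keeps rare-tail variants out of the
    threshold-selected set (they can still enter via ``must_include``).
    """
    if table.empty:
        raise ValueError("empty variant table")
    if not 0 < abundance_threshold <= 1:
        raise ValueError(
            f"abundance_threshold must be in (0, 1], got {abundance_threshold}"
        )
    if seed is None:
        matched = table[table["matched"]]
        seed = (matched.iloc[0] if len(matched) else table.iloc[0])["variant"]
    seed = iupac.normalize(seed)
    var_len = len(table.iloc[0]["variant"])
    if len(seed) != var_len:
        raise ValueError(
            f"seed length {len(seed)} != variant length {var_len}"
        )
    for o in must_include:
        if len(iupac.normalize(o)) != var_len:
            raise ValueError(
                f"curated oligo {o!r} length {len(o)} != variant length "
                f"{var_len}"
            )

    selected = table["overall_abundance"] > abundance_threshold
    if exclude_possible_errors:
        selected &= ~table["possible_error"]
    justification: dict[str, str] = {seed: "seed"}
    for v in table.loc[selected, "variant"]:
        justification.setdefault(v, f"observed>{abundance_threshold:g}")
    for o in must_include:
        justification.setdefault(iupac.normalize(o), "curated")
    oligos = OligoSet(primer_name, justification.keys())

    members = set(oligos)
    datasets = _dataset_names(table)
    achieved = {
        ds: float(
            table.loc[table["variant"].isin(members), f"freq_{ds}"].sum()
        )
        for ds in datasets
    }
    overall = float(
        table.loc[table["variant"].isin(members), "overall_abundance"].sum()
    )
    union = degenerate_union(list(oligos))
    return MixtureDesign(
        primer_name=primer_name,
        seed=seed,
        oligos=oligos,
        justification=justification,
        achieved_coverage=achieved,
        overall_coverage=overall,
        degenerate_union=union,
        union_degeneracy=iupac.degeneracy(union),
        abundance_threshold=abundance_threshold,
    )


def compare_mixture_vs_degenerate(
    design: MixtureDesign, table: Optional[pd.DataFrame] = None
) -> dict:
    """Contrast the explicit mixture with its fully degenerate consensus.

    Reports the mixture size, the degeneracy of the minimal IUPAC union
    covering it, their ratio, and how many union expansions were never
    observed in the data (redundant oligos a degenerate synthesis would
    waste on nothing). Without a table, redundancy is counted against the
    mixture itself.
    """
    expansions = iupac.expand(
        design.degenerate_union,
        cap=max(iupac.DEFAULT_EXPANSION_CAP, design.union_degeneracy),
    )
    observed = (
        set(table["variant"]) if table is not None else set(design.oligos)
    )
    redundant = [e for e in expansions if e not in observed]
    return {
        "primer_name": design.primer_name,
        "n_oligos": design.n_oligos,
        "degenerate_union": design.degenerate_union,
        "union_degeneracy": design.union_degeneracy,
        "degeneracy_ratio": design.union_degeneracy / design.n_oligos,
        "n_redundant_oligos": len(redundant),
    }


def suggest_degeneracies(
    table: pd.DataFrame,
    primer: DegeneratePrimer,
    max_added: int = 5,
) -> pd.DataFrame:
    """Rank single-position IUPAC widenings by unmatched abundance recovered.

    For each primer position, consider the unmatched variants whose only
    mismatch is at that position (those are exactly the variants a single
    widening can rescue); the suggested code is the minimal IUPAC set
    covering the primer's current set plus those variants' bases there.
    Rows: ``position`` (1-based, 5'->3' on the primer), ``old_code``,
    ``new_code``, ``abundance_gained``, ``new_degeneracy``. Sorted by gain
    descending; empty for a fully matched table.
    """
    pseq = primer.sequence
    unmatched = table[~table["matched"]]
    rows = []
    for pos in range(len(pseq)):
        gain = 0.0
        extra_bases: set[str] = set()
        for _, row in unmatched.iterrows():
            v = row["variant"]
            mm = [
                i for i in range(len(pseq))
                if v[i] not in iupac.iupac_set(pseq[i])
            ]
            if mm == [pos]:
                gain += row["overall_abundance"]
                extra_bases.add(v[pos])
        if not extra_bases:
            continue
        new_set = iupac.iupac_set(pseq[pos]) | extra_bases
        new_code = iupac.code_for_set(new_set)
        new_seq = pseq[:pos] + new_code + pseq[pos + 1:]
        rows.append(
            {
                "position": pos + 1,
                "old_code": pseq[pos],
                "new_code": new_code,
                "abundance_gained": gain,
                "new_degeneracy": iupac.degeneracy(new_seq),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["position", "old_code", "new_code", "abundance_gained",
                 "new_degeneracy"],
    )
    out = out.sort_values(
        ["abundance_gained", "position"], ascending=[False, True]
    ).head(max_added).reset_index(drop=True)
    return out
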