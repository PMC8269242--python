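"""Synthetic fixture generator with recorded ground truth.

Emulates the inputs the evaluation pipeline consumes in the field — reads
randomly sheared from SSU rRNA molecules, aligned to a group-specific
reference — without any external data. Per organismal group it builds a
random reference with the primer windows embedded at their configured
coordinates, shears uniform-start fixed-length reads, and makes every read
that fully covers a primer window draw its window sequence from a variant
pool with planted frequencies. Ground truth (per-read variant, group,
qualifies-for-extraction flag, planted quality class) is recorded so that
downstream recovery can be checked exactly.

Everything is deterministic given the spec seed, byte-for-byte, with
independent substreams for references, per-sample reads, and abundance
tables.

What this emulates and what it does not: read starts are uniform (no GC or
coverage bias), errors are off by default, and quality is two-level
(pass/fail) so the quality filter's outcome is exactly predictable. It is a
test harness for the arithmetic, not a community simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from . import iupac
from .primers import BUILTIN_PRIMERS, DegeneratePrimer

# Planted variant-pool frequencies used by the default spec: a dominant
# perfect match at 0.75 with a short tail of 1/2/3-mismatch variants.
DEFAULT_POOL_FREQS = (0.75, 0.15, 0.07, 0.03)


@dataclass
class SimulationSpec:
    """All knobs for the generator, with study-scale defaults."""

    seed: int = 0
    reference_length: int = 1600
    read_length: int = 150
    n_reads: int = 2000          # per sample per group
    n_samples: int = 10
    groups: tuple[str, ...] = ("Bacteria",)
    primers: tuple[DegeneratePrimer, ...] = (
        BUILTIN_PRIMERS["515Y"], BUILTIN_PRIMERS["926R"],
    )
    # primer name -> group -> ((window_seq, freq), ...), reference orientation
    pools: dict = field(default_factory=dict)
    flank: int = 5
    fail_fraction: float = 0.05   # reads emitted with the failing quality
    pass_quality: int = 40
    fail_quality: int = 2
    substitution_rate: float = 0.0
    # paired abundance tables
    n_taxa: int = 12
    n_table_groups: int = 5
    n_table_samples: int = 10
    table_noise_sigma: float = 0.0
    depth_split_m: float = 150.0

    def __post_init__(self):
        if not self.pools:
            self.pools = {
                p.name: {g: default_pool(p) for g in self.groups}
                for p in self.primers
            }
        for p in self.primers:
            if self.read_length <= len(p) + 10:
                raise ValueError(
                    f"read_length {self.read_length} must exceed primer "
                    f"{p.name} length {len(p)} by more than 10"
                )
            if p.ref_end > self.reference_length:
                raise ValueError(
                    f"primer {p.name} window ends at {p.ref_end}, beyond the "
                    f"reference of length {self.reference_length}"
                )
            for g, pool in self.pools[p.name].items():
                total = sum(f for _, f in pool)
                if not math.isclose(total, 1.0, abs_tol=1e-9):
                    raise ValueError(
                        f"pool frequencies for {p.name}/{g} sum to {total}, "
                        "expected 1"
                    )
                for s, _ in pool:
                    if len(s) != len(p):
                        raise ValueError(
                            f"pool variant {s!r} for {p.name}/{g} has length "
                            f"{len(s)}, expected {len(p)}"
                        )


def default_pool(
    primer: DegeneratePrimer,
    freqs: Sequence[float] = DEFAULT_POOL_FREQS,
) -> tuple[tuple[str, float], ...]:
    """Deterministic variant pool: one perfect match, then k-mismatch variants.

    The k-th tail variant mutates the first k positions of the window to the
    alphabetically first base outside the primer's IUPAC set there, so its
    mismatch count is exactly k by construction.
    """
    pattern = primer.binding_pattern
    perfect = iupac.expand(pattern)[0]
    pool = [(perfect, freqs[0])]
    for k, f in enumerate(freqs[1:], start=1):
        bases = list(perfect)
        for pos in range(k):
            outside = sorted(set("ACGT") - iupac.iupac_set(pattern[pos]))
            bases[pos] = outside[0]
        pool.append(("".join(bases), f))
    return tuple(pool)


def simulate_reference(spec: SimulationSpec) -> dict[str, str]:
    """One random reference per group with primer-pool consensus windows."""
    refs: dict[str, str] = {}
    for gi, group in enumerate(spec.groups):
        rng = np.random.default_rng([spec.seed, 0, gi])
        seq = rng.choice(list("ACGT"), size=spec.reference_length)
        seq = list("".join(seq))
        for p in spec.primers:
            pool = spec.pools[p.name][group]
            consensus = max(pool, key=lambda vf: vf[1])[0]
            seq[p.ref_start - 1: p.ref_end] = list(consensus)
        refs[group] = "".join(seq)
    return refs


def _qualifies(spec: SimulationSpec, primer: DegeneratePrimer,
               start: int) -> tuple[bool, bool]:
    """(covers window, meets one-sided flank rule) for a read at 0-based start."""
    end = start + spec.read_length
    w0, w1 = primer.ref_start - 1, primer.ref_end
    covers = start <= w0 and end >= w1
    flank_ok = start <= w0 - spec.flank or end >= w1 + spec.flank
    return covers, covers and flank_ok


def simulate_reads(
    spec: SimulationSpec, out_dir: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Write per-sample-per-group FASTQ + SAM plus truth/sidecar TSVs.

    Returns (manifest, reads_truth, planted_variants). Every emitted read has
    exactly one row in ``reads_truth``; ``planted_variants`` has one row per
    read x window-covering primer with the drawn variant and the
    qualifies-for-extraction flag under the one-sided flank rule.
    """
    out = Path(out_dir)
    (out / "refs").mkdir(parents=True, exist_ok=True)
    (out / "reads").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    refs = simulate_reference(spec)
    for group, seq in refs.items():
        with open(out / "refs" / f"{group}.fasta", "w") as fh:
            fh.write(f">{_ref_name(group)}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")

    samples = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    manifest_rows, truth_rows, planted_rows = [], [], []
    for si, sample in enumerate(samples):
        for gi, group in enumerate(spec.groups):
            rng = np.random.default_rng([spec.seed, 1, si, gi])
            ref = refs[group]
            ref_name = _ref_name(group)
            sam_path = out / "reads" / f"{sample}_{group}.sam"
            fq_path = out / "reads" / f"{sample}_{group}.fastq"
            header = {
                "HD": {"VN": "1.6", "SO": "unknown"},
                "SQ": [{"SN": ref_name, "LN": len(ref)}],
            }
            starts = rng.integers(
                0, len(ref) - spec.read_length + 1, size=spec.n_reads
            )
            fails = rng.random(spec.n_reads) < spec.fail_fraction
            with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam, \
                    open(fq_path, "w") as fq:
                for i in range(spec.n_reads):
                    start = int(starts[i])
                    read_id = f"{sample}:{group}:r{i:06d}"
                    bases = list(ref[start: start + spec.read_length])
                    for p in spec.primers:
                        covers, ok = _qualifies(spec, p, start)
                        if not covers:
                            continue
                        pool = spec.pools[p.name][group]
                        seqs = [s for s, _ in pool]
                        probs = np.array([f for _, f in pool])
                        pick = rng.choice(len(seqs), p=probs / probs.sum())
                        variant = seqs[pick]
                        w0 = p.ref_start - 1 - start
                        bases[w0: w0 + len(p)] = list(variant)
                        planted_rows.append(
                            {
                                "read_id": read_id,
                                "sample_id": sample,
                                "group": group,
                                "primer": p.name,
                                "variant": variant,
                                "qualifies": ok,
                            }
                        )
                    if spec.substitution_rate > 0:
                        hits = rng.random(spec.read_length) \
                            < spec.substitution_rate
                        for j in np.flatnonzero(hits):
                            bases[j] = rng.choice(
                                sorted(set("ACGT") - {bases[j]})
                            )
                    read_seq = "".join(bases)
                    q = spec.fail_quality if fails[i] else spec.pass_quality
                    qual_str = chr(q + 33) * spec.read_length
                    a = pysam.AlignedSegment(sam.header)
                    a.query_name = read_id
                    a.query_sequence = read_seq
                    a.flag = 0
                    a.reference_id = 0
                    a.reference_start = start
                    a.mapping_quality = 60
                    a.cigarstring = f"{spec.read_length}M"
                    a.query_qualities = pysam.qualitystring_to_array(qual_str)
                    sam.write(a)
                    fq.write(f"@{read_id}\n{read_seq}\n+\n{qual_str}\n")
                    truth_rows.append(
                        {
                            "read_id": read_id,
                            "sample_id": sample,
                            "group": group,
                            "start_1based": start + 1,
                            "low_quality": bool(fails[i]),
                        }
                    )
            manifest_rows.append(
                {
                    "sample_id": sample,
                    "group": group,
                    "reference": ref_name,
                    "sam": str(sam_path),
                    "fastq": str(fq_path),
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample_id", "group", "start_1based",
                 "low_quality"],
    )
    planted = pd.DataFrame(
        planted_rows,
        columns=["read_id", "sample_id", "group", "primer", "variant",
                 "qualifies"],
    )
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth" / "reads.tsv", sep="\t", index=False)
    planted.to_csv(out / "truth" / "planted_variants.tsv", sep="\t",
                   index=False)
    truth[["read_id", "group"]].to_csv(
        out / "truth" / "groups.tsv", sep="\t", index=False, header=False
    )
    return manifest, truth, planted


def _ref_name(group: str) -> str:
    return f"{group}_SSU_ref"


def simulate_paired_tables(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Paired taxon x sample tables for the concordance stage, plus truth.

    The metagenome table is a Dirichlet composition per sample; the amplicon
    table equals it up to multiplicative lognormal noise of scale
    ``table_noise_sigma`` per cell (sigma = 0 gives exact equality before
    renormalization). Returns (amplicon, metagenome, taxon->group mapping,
    sample metadata with depth_m).
    """
    rng = np.random.default_rng([spec.seed, 2])
    taxa = [f"T{i + 1:03d}" for i in range(spec.n_taxa)]
    samples = [f"S{i + 1:02d}" for i in range(spec.n_table_samples)]
    mapping = {
        t: f"G{(i % spec.n_table_groups) + 1}" for i, t in enumerate(taxa)
    }
    met = rng.dirichlet(np.ones(spec.n_taxa), size=len(samples)).T
    noise = (
        np.exp(rng.normal(0.0, spec.table_noise_sigma, met.shape))
        if spec.table_noise_sigma > 0
        else np.ones_like(met)
    )
    amp = met * noise
    amp = amp / amp.sum(axis=0, keepdims=True)
    metagenome = pd.DataFrame(met, index=taxa, columns=samples)
    amplicon = pd.DataFrame(amp, index=taxa, columns=samples)
    depths = np.where(
        np.arange(len(samples)) % 2 == 0, 5.0, spec.depth_split_m + 150.0
    )
    metadata = pd.DataFrame({"sample_id": samples, "depth_m": depths})
    return amplicon, metagenome, mapping, metadata


def simulate_run(spec: SimulationSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture set (reads + tables) under ``out_dir``."""
    out = Path(out_dir)
    simulate_reads(spec, out)
    amp, met, mapping, metadata = simulate_paired_tables(spec)
    tables = out / "tables"
    tables.mkdir(exist_ok=True)
    amp.to_csv(tables / "amplicon.tsv", sep="\t", index_label="taxon")
    met.to_csv(tables / "metagenome.tsv", sep="\t", index_label="taxon")
    pd.Series(mapping, name="group").to_csv(
        tables / "mapping.tsv", sep="\t", index_label="taxon"
    )
    metadata.to_csv(tables / "metadata.tsv", sep="\t", index=False)
    return {
        "manifest": out / "manifest.tsv",
        "reads_truth": out / "truth" / "reads.tsv",
        "planted_variants": out / "truth" / "planted_variants.tsv",
        "groups": out / "truth" / "groups.tsv",
        "amplicon": tables / "amplicon.tsv",
        "metagenome": tables / "metagenome.tsv",
        "mapping": tables / "mapping.tsv",
        "metadata": tables / "metadata.tsv",
    }
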