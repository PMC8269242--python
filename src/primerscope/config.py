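"""Run configuration: primers, pairs, thresholds, and paths from YAML.

A run config gathers everything a pipeline stage needs. Template::

    primers:
      - name: 515Y
        sequence: GTGYCAGCMGCCGCGGTAA
        orientation: forward
        ref_start: 515
      - 926R                # bare name -> built-in definition
    pairs:
      - [515Y, 926R]
    thresholds:
      mismatch_levels: [0, 1, 2]
      exclusion_mismatches: 6
      min_mean_quality: 30
      design_abundance: 0.02
    flank: 5
    require_both_flanks: false
    pair_rule: product
    seed: 0

All keys are optional except ``primers``; unknown keys are rejected so typos
fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .primers import GROUPS, BUILTIN_PRIMERS, DegeneratePrimer


class ConfigError(ValueError):
    """Malformed run configuration; message points at the offending key."""


_KNOWN_KEYS = {
    "primers", "pairs", "thresholds", "flank", "require_both_flanks",
    "pair_rule", "seed", "simulation",
}
_KNOWN_THRESHOLDS = {
    "mismatch_levels", "exclusion_mismatches", "min_mean_quality",
    "design_abundance",
}


@dataclass
class RunConfig:
    primers: dict[str, DegeneratePrimer]
    pairs: list[tuple[str, str]] = field(default_factory=list)
    mismatch_levels: tuple[int, ...] = (0, 1, 2)
    exclusion_mismatches: int = 6
    min_mean_quality: float = 30.0
    design_abundance: float = 0.02
    flank: int = 5
    require_both_flanks: bool = False
    pair_rule: str = "product"
    seed: int = 0
    simulation: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "primers": {
                n: {
                    "sequence": p.sequence,
                    "orientation": p.orientation,
                    "reference": p.reference,
                    "ref_start": p.ref_start,
                    "ref_end": p.ref_end,
                    "targeted_groups": list(p.targeted_groups),
                }
                for n, p in self.primers.items()
            },
            "pairs": [list(p) for p in self.pairs],
            "mismatch_levels": list(self.mismatch_levels),
            "exclusion_mismatches": self.exclusion_mismatches,
            "min_mean_quality": self.min_mean_quality,
            "design_abundance": self.design_abundance,
            "flank": self.flank,
            "require_both_flanks": self.require_both_flanks,
            "pair_rule": self.pair_rule,
            "seed": self.seed,
        }


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; raises ConfigError on problems."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    unknown = set(doc) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(
            f"{path}: unknown keys {sorted(unknown)}; expected a subset of "
            f"{sorted(_KNOWN_KEYS)}"
        )
    if "primers" not in doc:
        raise ConfigError(f"{path}: missing required key 'primers'")

    primers: dict[str, DegeneratePrimer] = {}
    for entry in doc["primers"]:
        if isinstance(entry, str):
            if entry not in BUILTIN_PRIMERS:
                raise ConfigError(
                    f"{path}: primers: unknown built-in primer {entry!r}"
                )
            primers[entry] = BUILTIN_PRIMERS[entry]
            continue
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
        except (KeyError, ValueError) as e:
            raise ConfigError(f"{path}: primers: {e}") from e
        primers[primer.name] = primer

    pairs: list[tuple[str, str]] = []
    for pair in doc.get("pairs", []):
        if len(pair) != 2:
            raise ConfigError(f"{path}: pairs: {pair!r} is not a 2-list")
        f, r = pair
        for n in (f, r):
            if n not in primers:
                raise ConfigError(
                    f"{path}: pairs: primer {n!r} not defined under 'primers'"
                )
        if primers[f].orientation != "forward":
            raise ConfigError(f"{path}: pairs: {f!r} is not a forward primer")
        if primers[r].orientation != "reverse":
            raise ConfigError(f"{path}: pairs: {r!r} is not a reverse primer")
        pairs.append((f, r))

    th = doc.get("thresholds", {}) or {}
    bad = set(th) - _KNOWN_THRESHOLDS
    if bad:
        raise ConfigError(f"{path}: thresholds: unknown keys {sorted(bad)}")
    cfg = RunConfig(
        primers=primers,
        pairs=pairs,
        mismatch_levels=tuple(th.get("mismatch_levels", (0, 1, 2))),
        exclusion_mismatches=int(th.get("exclusion_mismatches", 6)),
        min_mean_quality=float(th.get("min_mean_quality", 30)),
        design_abundance=float(th.get("design_abundance", 0.02)),
        flank=int(doc.get("flank", 5)),
        require_both_flanks=bool(doc.get("require_both_flanks", False)),
        pair_rule=str(doc.get("pair_rule", "product")),
        seed=int(doc.get("seed", 0)),
        simulation=doc.get("simulation", {}) or {},
    )
    if cfg.pair_rule not in ("product", "min", "worst_case"):
        raise ConfigError(
            f"{path}: pair_rule: {cfg.pair_rule!r} not one of "
            "product/min/worst_case"
        )
    if not 0 < cfg.design_abundance <= 1:
        raise ConfigError(
            f"{path}: thresholds.design_abundance: {cfg.design_abundance} "
            "outside (0, 1]"
        )
    if cfg.exclusion_mismatches < 0 or cfg.min_mean_quality < 0:
        raise ConfigError(f"{path}: thresholds must be non-negative")
    return cfg
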