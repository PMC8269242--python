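"""Amplicon–metagenome concordance: aggregate, normalize, regress per sample.

Amplicon ASV tables and metagenome read-classification tables rarely share a
taxonomic resolution — a 150 bp metagenomic read may only be assignable to a
broad clade — so both tables are first collapsed onto a common set of groups
via an explicit taxon -> group mapping, normalized to relative abundances,
and then compared per sample with an ordinary least-squares fit of amplicon
on metagenome abundance. The per-sample coefficient of determination (R²) is
the concordance metric; a depth-stratified summary reports the fraction of
samples below an R² threshold in each stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_R2_THRESHOLD = 0.95
DEFAULT_DEPTH_SPLIT_M = 150.0
MIN_GROUPS_FOR_FIT = 3


@dataclass(frozen=True)
class ConcordanceResult:
    """Per-sample OLS fit of amplicon on metagenome relative abundance."""

    sample_id: str
    n_groups: int
    r_squared: Optional[float]
    slope: Optional[float]
    intercept: Optional[float]
    reason: Optional[str] = None  # set when no fit could be reported


def normalize_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to sum to 1; all-zero columns stay zero."""
    if (table.values < 0).any():
        raise ValueError("abundance table contains negative entries")
    sums = table.sum(axis=0)
    safe = sums.replace(0, np.nan)
    return table.div(safe, axis=1).fillna(0.0)


def aggregate_to_common_groups(
    amplicon: pd.DataFrame,
    metagenome: pd.DataFrame,
    mapping: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum taxon rows into shared groups; absent groups get explicit zeros.

    Both inputs are taxon x sample tables (counts or relative abundances).
    Every taxon present in either table must appear in ``mapping``; offenders
    are listed in the error. Outputs share an identical group index.
    """
    missing = sorted(
        (set(amplicon.index) | set(metagenome.index)) - set(mapping)
    )
    if missing:
        raise KeyError(
            f"{len(missing)} taxa missing from the group mapping: {missing}"
        )
    groups = sorted(set(mapping[t] for t in amplicon.index)
                    | set(mapping[t] for t in metagenome.index))

    def collapse(tbl: pd.DataFrame) -> pd.DataFrame:
        g = tbl.groupby([mapping[t] for t in tbl.index]).sum()
        return g.reindex(groups, fill_value=0.0)

    return collapse(amplicon), collapse(metagenome)


def regress(
    amplicon: pd.DataFrame,
    metagenome: pd.DataFrame,
    sample_id: str,
    log10: bool = False,
) -> ConcordanceResult:
    """OLS of amplicon on metagenome relative abundance for one sample.

    Both tables must already be aggregated to identical group indices; each
    column is normalized to the simplex before fitting, so the fit is
    invariant to a common positive rescaling of either table's raw counts.
    Groups absent (zero) from both sources are dropped; groups present in
    only one keep an explicit zero. Fits need at least three groups and
    nonconstant metagenome abundances; otherwise a null result carries the
    reason. ``log10`` fits on log10 abundance instead (zero-abundance groups
    are then dropped entirely); off by default.
    """
    if not amplicon.index.equals(metagenome.index):
        raise ValueError("tables are not aggregated to a common group index")
    x = normalize_columns(metagenome[[sample_id]])[sample_id]
    y = normalize_columns(amplicon[[sample_id]])[sample_id]
    keep = (x > 0) | (y > 0)
    x, y = x[keep], y[keep]
    if log10:
        pos = (x > 0) & (y > 0)
        x, y = np.log10(x[pos]), np.log10(y[pos])
    n = len(x)
    if n < MIN_GROUPS_FOR_FIT:
        return ConcordanceResult(
            sample_id, n, None, None, None,
            reason=f"only {n} groups with nonzero abundance",
        )
    if np.ptp(x.values) == 0:
        return ConcordanceResult(
            sample_id, n, None, None, None,
            reason="degenerate fit: metagenome abundances all equal",
        )
    fit = stats.linregress(x.values, y.values)
    return ConcordanceResult(
        sample_id, n, float(fit.rvalue**2), float(fit.slope),
        float(fit.intercept),
    )


def concordance_table(
    amplicon: pd.DataFrame,
    metagenome: pd.DataFrame,
    mapping: Mapping[str, str],
    log10: bool = False,
) -> pd.DataFrame:
    """Aggregate both tables and regress every shared sample column."""
    shared = [s for s in metagenome.columns if s in set(amplicon.columns)]
    if not shared:
        raise ValueError("no shared sample columns between the two tables")
    amp, met = aggregate_to_common_groups(amplicon, metagenome, mapping)
    rows = [regress(amp, met, s, log10=log10) for s in shared]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "n_groups": [r.n_groups for r in rows],
            "r_squared": [np.nan if r.r_squared is None else r.r_squared
                          for r in rows],
            "slope": [np.nan if r.slope is None else r.slope for r in rows],
            "intercept": [np.nan if r.intercept is None else r.intercept
                          for r in rows],
            "reason": [r.reason or "" for r in rows],
        }
    )


def depth_summary(
    results: pd.DataFrame,
    metadata: pd.DataFrame,
    depth_split_m: float = DEFAULT_DEPTH_SPLIT_M,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> pd.DataFrame:
    """Fraction of samples with R² below threshold, per depth stratum.

    ``metadata`` needs columns ``sample_id`` and ``depth_m``. Strata are
    depth <= split ("shallow") and depth > split ("deep"). Samples without a
    reported R² are left out of the fractions.
    """
    merged = results.merge(metadata[["sample_id", "depth_m"]], on="sample_id")
    merged = merged.dropna(subset=["r_squared"])
    merged["stratum"] = np.where(
        merged["depth_m"] > depth_split_m,
        f">{depth_split_m:g} m",
        f"<={depth_split_m:g} m",
    )
    out = (
        merged.groupby("stratum")
        .agg(
            n_samples=("r_squared", "count"),
            median_r2=("r_squared", "median"),
            fraction_below=(
                "r_squared", lambda s: float((s < r2_threshold).mean())
            ),
        )
        .reset_index()
    )
    out["r2_threshold"] = r2_threshold
    return out
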