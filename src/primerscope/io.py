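"""Canonical TSV dialect: tab-separated, UTF-8, '#'-prefixed header comments.

Every table the pipeline writes carries a comment header recording the tool
version, the parameters in force, and a digest of the configuration, so any
output file is self-describing and reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__


def config_digest(config: Mapping) -> str:
    """Short stable digest of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    meta: Optional[Mapping] = None,
    index: bool = False,
) -> None:
    """Write a DataFrame as TSV with a commented metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# primerscope {__version__}\n")
        fh.write("# coordinates: 1-based inclusive\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_abundance_tsv(path: str | Path) -> pd.DataFrame:
    """Read a taxon x sample abundance TSV (first column is the taxon id)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)
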