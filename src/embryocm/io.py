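"""TSV table I/O and run manifests.

The canonical on-disk dialect is tab-separated UTF-8 with "." decimals
and no thousands separators.  Fold-change columns are written with three
decimals so the qualitative sentinel round-trips as the exact string
``-99.000``.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig

#: Columns rendered with a fixed number of decimals on write.  Only the
#: fold change is formatted, so the qualitative sentinel serializes as
#: the exact string -99.000; every other numeric column keeps full
#: precision for lossless round-trips.
_DECIMALS = {"LogFCh": 3}

SCHEMAS = {
    "samples": ["sample_id", "cryo", "breed", "culture", "bull",
                "stage0h", "stage24h", "age", "D40", "D62", "Birth"],
    "impact": ["culture", "stage0h", "stage24h"],
    "hits": ["feature_id", "AUC", "P1", "LogFCh", "P2", "endpoint"],
}


class SchemaError(ValueError):
    pass


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col, nd in _DECIMALS.items():
        if col in out.columns:
            out[col] = out[col].map(
                lambda v, nd=nd: "" if pd.isna(v) else f"{float(v):.{nd}f}"
            )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def read_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path.name}: malformed table ({exc})") from exc
    if schema is not None:
        required = SCHEMAS[schema]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path.name}: missing column(s) {missing}")
    return df


def write_manifest(
    path: str | Path,
    config: RunConfig,
    row_counts: dict[str, int],
    overrides: dict | None = None,
) -> Path:
    """Record config hash, seed, versions and per-stage row counts."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "embryocm",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "overrides": overrides or {},
        "row_counts": row_counts,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
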