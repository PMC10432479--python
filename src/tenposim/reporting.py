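"""Result serialization: CSV tables with a JSON metadata sidecar.

CSV output is UTF-8 with a header row and '.' decimals; floats are
written with shortest round-trip repr so a re-read reproduces the table
exactly and identical runs produce byte-identical files.  The sidecar
records the configuration hash, seed and software version (no
timestamps, for reproducibility).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig


class ReportError(ValueError):
    pass


def write_results(table: pd.DataFrame, path, config: RunConfig | None = None,
                  seed: int | None = None) -> dict:
    """Write ``path`` (CSV) and ``path`` with ``.meta.json`` suffix.

    Returns the metadata dict.  An empty table produces a header-only CSV.
    """
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        table.to_csv(path, index=False, lineterminator="\n")
    except OSError as exc:
        raise ReportError(f"cannot write {path}: {exc}") from exc
    meta = {
        "version": __version__,
        "rows": int(table.shape[0]),
        "columns": list(table.columns),
        "seed": seed if seed is not None else
                (config.seed if config is not None else None),
        "config_hash": config.config_hash() if config is not None else None,
        "config": config.to_dict() if config is not None else None,
    }
    meta_path = path.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return meta


def read_results(path) -> pd.DataFrame:
    """Re-read a result table written by :func:`write_results`."""
    return pd.read_csv(Path(path))
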