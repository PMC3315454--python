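"""Tables and metadata on disk: CSV for numbers, JSON for provenance.

All writes are atomic (temp file in the target directory, then rename), so
a crashed run never leaves a partial result behind.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from contextlib import contextmanager
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

#: the documented table schemas, by kind
SCHEMAS = {
    "profile": ["x", "c0", "stderr"],
    "curve": ["x", "u", "se", "n"],
    "trajectory": ["t", "position"],
    "theory": ["x", "u_theory"],
    "sweep": ["N", "a", "b", "s", "phi", "lambda", "route", "se"],
}


@contextmanager
def atomic_write(path: Path | str):
    """Yield a temp-file handle that is renamed onto ``path`` on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(path: Path | str, table: pd.DataFrame, kind: str) -> None:
    """Write a table with the documented header for ``kind`` (atomic, UTF-8)."""
    cols = SCHEMAS[kind]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table missing columns {missing} for kind {kind!r}")
    with atomic_write(path) as fh:
        table[cols].to_csv(fh, index=False)


def read_table(path: Path | str, kind: str) -> pd.DataFrame:
    """Read a table, checking the header matches the expected schema."""
    df = pd.read_csv(path)
    cols = SCHEMAS[kind]
    if list(df.columns) != cols:
        raise ValueError(
            f"header mismatch in {path}: expected columns {cols}, "
            f"got {list(df.columns)}")
    return df


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_metadata(path: Path | str, config: dict, **extra) -> None:
    """Reproducibility record: full config, code version, timestamp."""
    record = {
        "config": _jsonable(config),
        "code_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    record.update(_jsonable(extra))
    with atomic_write(path) as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
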