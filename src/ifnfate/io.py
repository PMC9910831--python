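"""File schemas and loaders for clone-level fluctuation tables.

Canonical tabular dialect is TSV with an explicit header
``clone_id, generation, day, n_cells, n_responders[, fraction]``; CSV is
accepted on read.  All files store fractions on [0, 1]; percentages appear
only at reporting boundaries.  Exports of external clone-level deposits
can be loaded after being reshaped to this schema.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .lineage import DATASET_COLUMNS, FluctuationDataset

__all__ = ["load_clone_table", "write_clone_table", "write_manifest"]

REQUIRED_COLUMNS = ["clone_id", "generation", "day", "n_cells", "n_responders"]


class CloneTableError(ValueError):
    """Malformed clone table (message lists the offending lines)."""


def load_clone_table(path) -> FluctuationDataset:
    """Read a clone-level TSV/CSV table into a :class:`FluctuationDataset`.

    The fraction column is recomputed from counts when absent.  Schema
    violations (missing columns, non-numeric values, ``n_responders >
    n_cells``) raise :class:`CloneTableError` naming the offending file
    lines (1-based, header = line 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else None
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CloneTableError(f"{path}: missing required columns {missing}")

    bad_lines: list[str] = []
    for col in ("generation", "day", "n_cells", "n_responders"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[numeric.isna()]:
            bad_lines.append(f"line {idx + 2}: non-numeric {col}={df.loc[idx, col]!r}")
        df[col] = numeric
    if not bad_lines:
        over = df["n_responders"] > df["n_cells"]
        for idx in df.index[over]:
            bad_lines.append(
                f"line {idx + 2}: n_responders={df.loc[idx, 'n_responders']} "
                f"> n_cells={df.loc[idx, 'n_cells']}"
            )
        neg = (df["n_cells"] <= 0) | (df["n_responders"] < 0)
        for idx in df.index[neg]:
            bad_lines.append(f"line {idx + 2}: invalid counts")
    if bad_lines:
        raise CloneTableError(f"{path}: malformed rows:\n  " + "\n  ".join(bad_lines))

    df["generation"] = df["generation"].astype(int)
    df["n_cells"] = df["n_cells"].astype(int)
    df["n_responders"] = df["n_responders"].astype(int)
    if "fraction" not in df.columns:
        df["fraction"] = df["n_responders"] / df["n_cells"]
    return FluctuationDataset(
        records=df[DATASET_COLUMNS].copy(), metadata={"source": str(path)}
    )


def write_clone_table(dataset: FluctuationDataset, path) -> None:
    dataset.records.to_csv(path, sep="\t", index=False)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_manifest(path, seed: int, config: dict) -> dict:
    """Write the reproducibility manifest (version, seed, config hash).

    Deliberately timestamp-free so identical config + seed gives
    byte-identical outputs.
    """
    from . import __version__

    manifest = {
        "package": "ifnfate",
        "version": __version__,
        "seed": seed,
        "config_sha256": config_hash(config),
        "config": config,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
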