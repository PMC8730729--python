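"""Readers and writers for the package's delimited-text schemas.

Every table is UTF-8, tab-delimited, with optional ``#``-prefixed comment
lines at the top.  Schemas:

``peptides.tsv``
    peptide_id, protein_ids (semicolon-joined), rep1..repN (integer counts).
``proteins.tsv``
    protein_id, length_aa.
``traces.tsv``
    event_id, movie_id, frame, time_s, position_um, channel2_present (0/1).
``rois.tsv``
    cell_id, group, centrosome_intensity, whole_cell_intensity,
    centrosome_area, whole_cell_area.
``tubules.tsv``
    cell_id, tubule_id, max_length_um, moved_from_origin (0/1).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_table",
    "write_table",
    "read_truth",
    "write_truth",
]


def write_table(df: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write *df* as a tab-delimited UTF-8 file, optionally with a header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            if comment:
                for line in comment.splitlines():
                    fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"could not write table to {path}: {exc}") from exc


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a tab-delimited table, skipping '#' comment lines."""
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except OSError as exc:
        raise OSError(f"could not read table from {path}: {exc}") from exc


def write_truth(obj: dict, path) -> None:
    """Serialize a ground-truth record (JSON, sorted keys for determinism)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_truth(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
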