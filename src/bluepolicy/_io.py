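"""Deterministic output writing and run manifests.

All machine outputs are CSV with a fixed column order, LF line endings
and fixed numeric formatting (6 significant digits for proportions), so
repeated runs over identical inputs are byte-identical and golden-file
tests can compare raw bytes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = ["write_frame", "sha256_file", "write_manifest"]


def _fmt(value: object) -> str:
    if pd.isna(value):
        return ""
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def write_frame(frame: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """Write a DataFrame as deterministic CSV (LF, %.6g floats)."""
    path = Path(path)
    out = frame.reset_index() if index else frame
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(str(c) for c in out.columns) + "\n")
        for row in out.itertuples(index=False):
            fh.write(",".join(_fmt(v) for v in row) + "\n")
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    inputs: dict[str, str],
    outputs: list[str],
    seed: int | None = None,
    extra: dict | None = None,
) -> Path:
    """Write manifest.json recording input digests and output files."""
    from . import __version__

    manifest = {
        "command": command,
        "tool_version": __version__,
        "inputs": inputs,
        "outputs": sorted(outputs),
    }
    if seed is not None:
        manifest["seed"] = seed
    if extra:
        manifest.update(extra)
    path = Path(out_dir) / "manifest.json"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
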