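"""Run manifests: tie every output file to the seeds, settings and library
versions that produced it.

A manifest is written next to each CLI output (``<out>.manifest.json``),
even when the command fails (then with an ``error`` record and whatever
outputs exist).  Output files themselves contain no timestamps, so a rerun
with the same seed and config is byte-identical; the manifest records the
wall-clock time and version drift that legitimately vary between runs.
"""

from __future__ import annotations

import hashlib
import json
import os
from datetime import datetime, timezone
from importlib import metadata

_TRACKED_LIBS = ("mdsc", "numpy", "pandas", "scipy", "scikit-learn", "xgboost")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _versions() -> dict[str, str]:
    out = {}
    for lib in _TRACKED_LIBS:
        try:
            out[lib] = metadata.version(lib)
        except metadata.PackageNotFoundError:
            out[lib] = "unknown"
    return out


def manifest_path(out_path) -> str:
    return f"{out_path}.manifest.json"


def write_manifest(
    out_path,
    command: str,
    params: dict,
    inputs: list | None = None,
    outputs: list | None = None,
    error: str | None = None,
) -> str:
    """Write the manifest for ``out_path`` and return its path."""
    record = {
        "command": command,
        "params": params,
        "library_versions": _versions(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            str(p): file_digest(p) for p in (inputs or []) if os.path.exists(p)
        },
        "outputs": {
            str(p): file_digest(p) for p in (outputs or []) if os.path.exists(p)
        },
    }
    if error is not None:
        record["error"] = error
    path = manifest_path(out_path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
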