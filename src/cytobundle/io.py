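"""Tidy output writers and run manifests."""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path


def write_tidy_csv(df, path, header: dict | None = None) -> Path:
    """Write one-observation-per-row CSV, with key=value comment lines first."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}={val!r}\n")
        df.to_csv(fh, index=False)
    return path


def write_manifest(path, config: dict) -> Path:
    """Record package version and the fully resolved configuration as JSON."""
    try:
        pkg_version = version("cytobundle")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"package": "cytobundle", "version": pkg_version,
                                "config": config}, indent=2, default=str))
    return path
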