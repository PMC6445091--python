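"""Table output and run manifests.

All outputs are plain tab-separated tables with a header row, each
accompanied by a JSON manifest (configuration hash, seed, solver
settings, package version, command) sufficient to regenerate the table
exactly.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__

__all__ = ["write_table", "write_manifest", "config_hash"]


def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping."""
    canonical = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
    return path


def write_manifest(
    path: str | Path,
    config: dict,
    command: str,
    seed: int | None = None,
    extra: dict | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "nfixclim",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config_sha256_16": config_hash(config),
        "solver": config.get("solver", {}),
        "written_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
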