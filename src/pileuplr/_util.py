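"""Provenance helpers shared by the CLI workflows."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance_lines(config: dict, inputs: list | None = None) -> list[str]:
    """Comment lines recording tool version, config hash, seed, and inputs."""
    from . import __version__

    lines = [
        f"pileuplr {__version__}",
        f"config_hash {config_hash(config)}",
        f"seed {config.get('seed')}",
    ]
    for p in inputs or []:
        lines.append(f"input {Path(p).name} sha256:{file_checksum(p)}")
    return lines
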