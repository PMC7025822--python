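"""Run-provenance manifest: resolved config, seed, config hash, version."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

logger = logging.getLogger("fishkin")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: dict, seed: int | None) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    logger.info("seed=%s config_hash=%s", seed, manifest["config_hash"])
    return path
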