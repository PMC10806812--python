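"""Run manifests: enough metadata to re-run a command bit-identically
(for its deterministic stages)."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    command: str
    version: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    timestamp: Optional[str] = None

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _sha256(p)

    def write(self, path: str | Path) -> None:
        data = asdict(self)
        data["config_hash"] = config_hash(self.config)
        data["timestamp"] = self.timestamp or time.strftime("%Y-%m-%dT%H:%M:%S")
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True, default=str))
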