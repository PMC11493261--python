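"""Run manifests: tie every emitted artifact to config, seeds and version."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Collects stage metadata and file digests for one pipeline run."""

    def __init__(self, config_snapshot: dict, seed: int, version: str) -> None:
        self.data = {
            "version": version,
            "seed": seed,
            "config": config_snapshot,
            "started": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "stages": {},
            "files": {},
        }

    def record_stage(self, name: str, seed: int, **info) -> None:
        self.data["stages"][name] = {
            "seed": seed,
            "time": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            **info}

    def record_file(self, path: str | Path, stage: str) -> None:
        path = Path(path)
        self.data["files"][str(path)] = {
            "stage": stage, "sha256": _sha256(path),
            "bytes": path.stat().st_size}

    def record_tree(self, root: str | Path, stage: str,
                    suffixes: tuple[str, ...] = (".png", ".jpeg", ".json",
                                                 ".csv", ".npz")) -> None:
        root = Path(root)
        for p in sorted(root.rglob("*")):
            if p.is_file() and p.suffix in suffixes:
                self.record_file(p, stage)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.data["finished"] = datetime.datetime.now(
            datetime.timezone.utc).isoformat()
        path.write_text(json.dumps(self.data, indent=2, default=str))
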