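"""JSONL manifests tying sample files to labels and test types."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .tokens import FeatureSequence, TokenInventory, read_sequence_file

__all__ = ["ManifestRecord", "Manifest", "load_manifest", "save_manifest"]


@dataclass
class ManifestRecord:
    id: str
    path: str = ""
    label: Optional[int] = None
    test_type: str = ""


@dataclass
class Manifest:
    records: list[ManifestRecord] = field(default_factory=list)
    base_dir: Optional[str] = None  # relative record paths resolve here

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def require_labels(self) -> None:
        missing = [r.id for r in self.records if r.label is None]
        if missing:
            raise ValueError(f"records without labels: {missing[:5]}"
                             f"{' …' if len(missing) > 5 else ''}")

    def load_sequences(self, inv: TokenInventory,
                       base_dir: str | Path | None = None) -> list[FeatureSequence]:
        base_dir = base_dir if base_dir is not None else self.base_dir
        base = Path(base_dir) if base_dir else None
        out = []
        for r in self.records:
            p = Path(r.path)
            if base and not p.is_absolute():
                p = base / p
            seq = read_sequence_file(p, inv, sample_id=r.id, label=r.label)
            seq.test_type = r.test_type
            out.append(seq)
        return out


def load_manifest(path: str | Path, check_paths: bool = True) -> Manifest:
    """Read and validate a JSONL manifest (one record per line)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ManifestRecord] = []
    seen: set[str] = set()
    base = path.parent
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as e:
            raise ValueError(f"{path}:{lineno}: malformed JSON ({e.msg})") from None
        if not isinstance(obj, dict) or "id" not in obj:
            raise ValueError(f"{path}:{lineno}: record must be an object with an 'id'")
        rid = str(obj["id"])
        if rid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate id {rid!r}")
        seen.add(rid)
        label = obj.get("label")
        if label is not None and label not in (0, 1):
            raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {label!r}")
        rec = ManifestRecord(id=rid, path=str(obj.get("path", "")),
                             label=label, test_type=str(obj.get("test_type", "")))
        if check_paths and rec.path:
            p = Path(rec.path)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"{path}:{lineno}: missing file {rec.path}")
        records.append(rec)
    if not records:
        warnings.warn(f"{path}: empty manifest")
    return Manifest(records, base_dir=str(base))


def save_manifest(manifest: Manifest, path: str | Path) -> None:
    lines = []
    for r in manifest.records:
        obj = {"id": r.id, "path": r.path, "test_type": r.test_type}
        if r.label is not None:
            obj["label"] = r.label
        lines.append(json.dumps(obj, ensure_ascii=False))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
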