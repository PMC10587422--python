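"""File I/O: FASTA, BED3+name intervals, per-window label files, YAML config.

All readers and writers are mutually inverse on valid data.  Coordinates are
0-based half-open; a BED line with ``end <= start`` denotes an interval that
wraps through the origin of a circular sequence and is only accepted when
``circular=True``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dataprep import BindingInterval, CircSequence, LabeledWindow

log = logging.getLogger(__name__)


def read_fasta(path, circular: bool = True) -> list[CircSequence]:
    """FASTA records with uppercasing and T->U normalization, in file order."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(CircSequence(id=rec.id, bases=str(rec.seq), circular=circular))
    return records


def write_fasta(seqs: list[CircSequence] | list[LabeledWindow], path) -> None:
    records = []
    for s in seqs:
        if isinstance(s, LabeledWindow):
            records.append(SeqRecord(Seq(s.sequence), id=s.seq_id, description=""))
        else:
            records.append(SeqRecord(Seq(s.bases), id=s.id, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_bed(path, circular: bool = True, known_ids: set[str] | None = None) -> list[BindingInterval]:
    """BED3+name intervals; validates ids against ``known_ids`` when given."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start and not circular:
                raise ValueError(
                    f"{path}:{lineno}: end <= start is only valid for circular sequences"
                )
            if known_ids is not None and seq_id not in known_ids:
                raise ValueError(f"{path}:{lineno}: unknown sequence id {seq_id!r}")
            out.append(BindingInterval(seq_id=seq_id, start=start, end=end))
    return out


def write_bed(intervals: list[BindingInterval], path, name: str = ".") -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\n")


def read_interactome_intervals(path) -> list[BindingInterval]:
    """Import shim for the two-column dialect ``id<TAB>start-end`` (1-based,
    inclusive) used by circRNA interaction tables; converts to 0-based
    half-open."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            seq_id, span = line.split("\t")
            s, e = span.split("-")
            out.append(BindingInterval(seq_id=seq_id, start=int(s) - 1, end=int(e)))
    return out


def write_labels(windows: list[LabeledWindow], path) -> None:
    """One line per window: ``id TAB comma-joined 0/1``."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.seq_id}\t{','.join(str(int(v)) for v in w.labels)}\n")


def read_labels(path) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            try:
                wid, arr = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>0,1,...'") from exc
            values = np.array([int(v) for v in arr.split(",")], dtype=np.int8)
            if not np.isin(values, (0, 1)).all():
                raise ValueError(f"{path}:{lineno}: labels must be 0 or 1")
            out[wid] = values
    return out


def read_windows(fasta_path, labels_path) -> list[LabeledWindow]:
    """Pair a window FASTA with its label file; lengths must agree."""
    seqs = read_fasta(fasta_path, circular=False)
    labels = read_labels(labels_path)
    out = []
    for s in seqs:
        if s.id not in labels:
            raise ValueError(f"window {s.id!r} missing from label file")
        lab = labels[s.id]
        if len(lab) != len(s.bases):
            raise ValueError(
                f"window {s.id!r}: label length {len(lab)} != sequence length {len(s.bases)}"
            )
        prov = "positive" if lab.sum() else "negative"
        out.append(LabeledWindow(seq_id=s.id, sequence=s.bases, labels=lab, provenance=prov))
    return out


def write_fold_assignments(fold_split, windows: list[LabeledWindow], path) -> None:
    with open(path, "w") as fh:
        fh.write("window_id\tfold\n")
        for w, f in zip(windows, fold_split.assignments):
            fh.write(f"{w.seq_id}\t{int(f)}\n")


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def write_manifest(out_dir, config: dict, seeds: dict[str, int]) -> Path:
    """Record the exact configuration and seeds of a run for reproducibility."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"config": config, "seeds": seeds}
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
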