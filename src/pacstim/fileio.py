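"""Recording container and file dialects.

A :class:`RecordingContainer` bundles equal-length multi-channel sample
arrays (microvolts), the sample rate, an annotation table (label, start s,
end s, free-form payload) and metadata (seed, config echo) — everything
needed to reconstruct an analysis or regenerate the data.

Two on-disk dialects, auto-detected by extension:

* text (``.csv`` / ``.tsv`` / ``.txt``): '#'-prefixed header with JSON
  metadata and one JSON line per annotation, then one delimited row per
  sample.  Values are printed with 17 significant digits (exact float64
  round trip).
* binary columnar (``.h5`` / ``.hdf5``): HDF5 with one float64 dataset per
  channel under ``/channels`` plus attributes; bit-exact round trip.

Conventions used across the package: times in seconds (float), sample
indices 0-based, intervals half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .spectral import EpochMask

__all__ = [
    "RecordingContainer",
    "RecordingFormatError",
    "ChannelLengthMismatchError",
    "UnknownFormatError",
    "read_recording",
    "write_recording",
]

ANNOTATION_COLUMNS = ["label", "start", "end", "payload"]


class RecordingFormatError(ValueError):
    """File exists but its header or body is malformed."""


class ChannelLengthMismatchError(RecordingFormatError):
    """Channel arrays differ in length."""


class UnknownFormatError(ValueError):
    """Extension maps to no known dialect."""


def empty_annotations() -> pd.DataFrame:
    return pd.DataFrame(columns=ANNOTATION_COLUMNS)


@dataclass
class RecordingContainer:
    """Multi-channel recording with annotations and provenance metadata."""

    channels: dict[str, np.ndarray]
    sample_rate: float
    annotations: pd.DataFrame = field(default_factory=empty_annotations)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ChannelLengthMismatchError(f"channel lengths differ: {lengths}")
        self.channels = {name: np.asarray(x, dtype=float) for name, x in self.channels.items()}
        total = self.duration
        for _, row in self.annotations.iterrows():
            if row["start"] < -1e-9 or row["end"] > total + 1e-9:
                raise ValueError(f"annotation {row['label']} exceeds recording bounds")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]

    def intervals(self, label: str) -> list[tuple[float, float]]:
        sel = self.annotations[self.annotations["label"] == label]
        return [(float(r["start"]), float(r["end"])) for _, r in sel.iterrows()]

    def epoch_mask(self, labels=("stim",), guard: float = 0.0) -> EpochMask:
        """Validity mask: False inside any annotation with one of *labels*."""
        spans = []
        for lab in labels:
            spans.extend(self.intervals(lab))
        return EpochMask.from_intervals(self.n_samples, self.sample_rate, spans, guard)


_TEXT_EXT = {".csv": ",", ".tsv": "\t", ".txt": "\t"}
_BINARY_EXT = {".h5", ".hdf5"}


def write_recording(rc: RecordingContainer, path) -> None:
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _TEXT_EXT:
        _write_text(rc, path, _TEXT_EXT[ext])
    elif ext in _BINARY_EXT:
        _write_hdf5(rc, path)
    else:
        raise UnknownFormatError(f"unknown recording extension {ext!r}")


def read_recording(path) -> RecordingContainer:
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _TEXT_EXT:
        return _read_text(path, _TEXT_EXT[ext])
    if ext in _BINARY_EXT:
        return _read_hdf5(path)
    raise UnknownFormatError(f"unknown recording extension {ext!r}")


def _annotation_records(rc: RecordingContainer) -> list[dict]:
    out = []
    for _, row in rc.annotations.iterrows():
        out.append(
            {
                "label": str(row["label"]),
                "start": float(row["start"]),
                "end": float(row["end"]),
                "payload": row["payload"] if isinstance(row["payload"], dict) else {},
            }
        )
    return out


def _annotations_frame(records: list[dict]) -> pd.DataFrame:
    if not records:
        return empty_annotations()
    return pd.DataFrame(records, columns=ANNOTATION_COLUMNS)


def _write_text(rc: RecordingContainer, path: Path, delim: str) -> None:
    names = list(rc.channels)
    lines = [
        "# pacstim recording v1",
        f"# sample_rate = {rc.sample_rate!r}",
        f"# channels = {','.join(names)}",
        f"# meta = {json.dumps(rc.metadata, sort_keys=True)}",
    ]
    for rec in _annotation_records(rc):
        lines.append(f"# annotation = {json.dumps(rec, sort_keys=True)}")
    cols = np.column_stack([rc.channels[n] for n in names])
    body = "\n".join(delim.join(f"{v:.17g}" for v in row) for row in cols)
    path.write_text("\n".join(lines) + "\n" + body + "\n", encoding="utf-8", newline="\n")


def _read_text(path: Path, delim: str) -> RecordingContainer:
    header: dict[str, str] = {}
    annotations: list[dict] = []
    rows: list[list[float]] = []
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# pacstim recording"):
            raise RecordingFormatError(f"{path}: missing recording header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, sep, value = line.lstrip("# ").partition("=")
                if not sep:
                    raise RecordingFormatError(f"{path}: malformed header line {line!r}")
                key, value = key.strip(), value.strip()
                if key == "annotation":
                    annotations.append(json.loads(value))
                else:
                    header[key] = value
            else:
                try:
                    rows.append([float(v) for v in line.split(delim)])
                except ValueError as exc:
                    raise RecordingFormatError(f"{path}: bad sample row {line!r}") from exc
    if "sample_rate" not in header or "channels" not in header:
        raise RecordingFormatError(f"{path}: header lacks sample_rate/channels")
    names = header["channels"].split(",")
    try:
        data = np.array(rows, dtype=float)
    except ValueError as exc:
        raise RecordingFormatError(f"{path}: ragged sample rows") from exc
    if data.ndim != 2 or data.shape[1] != len(names):
        raise RecordingFormatError(
            f"{path}: body has {data.shape[1] if data.ndim == 2 else '?'} columns, "
            f"header names {len(names)} channels"
        )
    return RecordingContainer(
        channels={n: data[:, j] for j, n in enumerate(names)},
        sample_rate=float(header["sample_rate"]),
        annotations=_annotations_frame(annotations),
        metadata=json.loads(header.get("meta", "{}")),
    )


def _write_hdf5(rc: RecordingContainer, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "pacstim recording v1"
        f.attrs["sample_rate"] = rc.sample_rate
        f.attrs["meta"] = json.dumps(rc.metadata, sort_keys=True)
        f.attrs["annotations"] = json.dumps(_annotation_records(rc), sort_keys=True)
        grp = f.create_group("channels")
        for name, x in rc.channels.items():
            grp.create_dataset(name, data=x)


def _read_hdf5(path: Path) -> RecordingContainer:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "pacstim recording v1":
            raise RecordingFormatError(f"{path}: missing recording format attribute")
        channels = {name: np.array(ds) for name, ds in f["channels"].items()}
        return RecordingContainer(
            channels=channels,
            sample_rate=float(f.attrs["sample_rate"]),
            annotations=_annotations_frame(json.loads(f.attrs.get("annotations", "[]"))),
            metadata=json.loads(f.attrs.get("meta", "{}")),
        )
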