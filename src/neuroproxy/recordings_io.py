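"""Continuous-recording data model and EDF/BrainVision I/O.

The montage mirrors a 27-channel EEG cap plus 16 non-cerebral ("noEEG")
electrodes: eight around the neck (``Neck1``..``Neck8``) and four on each
wrist (``WrL1``..``WrL4``, ``WrR1``..``WrR4``).  All signals are kept in
microvolts at a common sampling rate, annotated with eyes-closed (``OC``) /
eyes-open (``OA``) condition blocks.

EDF files are written with a built-in plain-EDF encoder (16-bit samples,
one-second data records, per-channel physical range covering the signal);
condition blocks and any extra metadata go to a JSON sidecar next to the
file.  Reading goes through :mod:`mne` and accepts both the sidecar and
EDF+/BrainVision annotations using the ``OC_1`` .. ``OA_4`` label
convention.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EEG_CHANNELS",
    "NOEEG_CHANNELS",
    "EEG_FEATURE_CHANNELS",
    "NOEEG_FEATURE_CHANNELS",
    "ChannelInfo",
    "Block",
    "Recording",
    "default_montage",
    "mini_montage",
    "role_from_label",
    "read_recording",
    "write_recording",
]

#: The 27 scalp electrodes of the recording montage.
EEG_CHANNELS = [
    "Fp1", "Fp2", "AF3", "AFz", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "C3", "Cz", "C4", "CP3", "CPz", "CP4", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "POz", "PO4", "O1", "Oz", "O2",
]

#: The 16 non-cerebral electrodes (neck ring and both wrists).
NOEEG_CHANNELS = [
    "Neck1", "Neck2", "Neck3", "Neck4", "Neck5", "Neck6", "Neck7", "Neck8",
    "WrL1", "WrL2", "WrL3", "WrL4", "WrR1", "WrR2", "WrR3", "WrR4",
]

#: Scalp channels used as classifier features.
EEG_FEATURE_CHANNELS = ["F3", "Fz", "C3", "Cz", "CP3", "CPz", "P3", "O1", "Oz"]

#: Non-cerebral channels used as classifier features.
NOEEG_FEATURE_CHANNELS = [
    "Neck2", "Neck4", "Neck5", "Neck6", "WrL2", "WrR1", "WrR2", "WrR4",
]

# Alternate spellings seen for the wrist electrodes.
_LABEL_ALIASES = {f"LWrist{i}": f"WrL{i}" for i in range(1, 5)}
_LABEL_ALIASES.update({f"RWrist{i}": f"WrR{i}" for i in range(1, 5)})

_CONDITIONS = ("OC", "OA")
_BLOCK_RE = re.compile(r"^(OC|OA)_(\d+)$")


def canonical_label(label: str) -> str:
    """Map alternate electrode spellings (LWrist2 -> WrL2) to canonical form."""
    return _LABEL_ALIASES.get(label, label)


def role_from_label(label: str, overrides: dict[str, str] | None = None) -> str:
    """Infer the channel role (``EEG`` / ``neck`` / ``wrist``) from its label.

    ``overrides`` maps labels to roles for montages that do not follow the
    prefix convention.
    """
    label = canonical_label(label)
    if overrides and label in overrides:
        return overrides[label]
    if label.startswith("Neck"):
        return "neck"
    if label.startswith(("WrL", "WrR")):
        return "wrist"
    return "EEG"


@dataclass(frozen=True)
class ChannelInfo:
    label: str
    role: str  # "EEG" | "neck" | "wrist"
    unit: str = "uV"


@dataclass(frozen=True)
class Block:
    """One condition block: half-open interval [onset, onset + duration)."""

    condition: str  # "OC" | "OA"
    repetition: int  # 1-based within condition
    onset: float  # seconds from recording start
    duration: float  # seconds

    @property
    def label(self) -> str:
        return f"{self.condition}_{self.repetition}"


@dataclass
class Recording:
    """Continuous multichannel recording in microvolts.

    ``data`` is channels x samples; ``blocks`` carry the OC/OA annotations.
    ``meta`` holds provenance (subject index, ground-truth simulation values,
    injected artifact events, ...).
    """

    sfreq: float
    channels: list[ChannelInfo]
    data: np.ndarray
    blocks: list[Block] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channels declared but data has "
                f"{self.data.shape[0]} rows"
            )
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channel_index(self, label: str) -> int:
        label = canonical_label(label)
        for i, c in enumerate(self.channels):
            if c.label == label:
                return i
        raise KeyError(f"channel {label!r} not in recording")

    def get(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        seen = set()
        for c in self.channels:
            if c.label in seen:
                raise ValueError(f"duplicate channel label {c.label!r}")
            seen.add(c.label)
        intervals = sorted((b.onset, b.onset + b.duration) for b in self.blocks)
        for (s0, e0), (s1, _) in zip(intervals, intervals[1:]):
            if s1 < e0 - 1e-9:
                raise ValueError("condition blocks overlap")
        for b in self.blocks:
            if b.condition not in _CONDITIONS:
                raise ValueError(f"unknown condition {b.condition!r}")
            if b.onset < -1e-9 or b.onset + b.duration > self.duration + 1e-9:
                raise ValueError(f"block {b.label} outside recorded duration")

    def copy(self) -> "Recording":
        return Recording(
            sfreq=self.sfreq,
            channels=list(self.channels),
            data=self.data.copy(),
            blocks=list(self.blocks),
            meta=dict(self.meta),
        )


def default_montage() -> list[ChannelInfo]:
    """The full 27 EEG + 16 noEEG montage."""
    return [ChannelInfo(l, role_from_label(l)) for l in EEG_CHANNELS + NOEEG_CHANNELS]


def mini_montage() -> list[ChannelInfo]:
    """A reduced montage for fast tests: 3 EEG + 2 neck + 1 wrist channels."""
    labels = ["Fz", "Pz", "Oz", "Neck2", "Neck4", "WrL2"]
    return [ChannelInfo(l, role_from_label(l)) for l in labels]


# ---------------------------------------------------------------------------
# EDF writing (plain EDF, 16-bit, one-second records)
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a :class:`Recording` to plain EDF plus a JSON annotation sidecar.

    The per-channel physical range is chosen to cover the signal; amplitudes
    are therefore always representable and round-trip error is bounded by the
    16-bit quantization step.  Non-finite samples raise instead of being
    clipped.  Blocks and ``meta`` go to ``<stem>.json`` next to the EDF.
    """
    path = Path(path)
    recording.validate()
    if recording.n_samples == 0:
        raise ValueError("cannot write an empty recording (0 samples)")
    sfreq = recording.sfreq
    spr = int(round(sfreq))  # samples per 1-s record
    if abs(sfreq - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / spr))

    data = recording.data
    pmin = np.floor(np.min(data, axis=1))
    pmax = np.ceil(np.max(data, axis=1))
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    header = bytearray()
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)  # local patient id (anonymous)
    header += _edf_field("Startdate X", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(str(256 * (n_ch + 1)), 8)
    header += _edf_field("", 44)
    header += _edf_field(str(n_records), 8)
    header += _edf_field("1", 8)  # record duration, seconds
    header += _edf_field(str(n_ch), 4)
    for c in recording.channels:
        header += _edf_field(c.label, 16)
    for _ in range(n_ch):
        header += _edf_field("", 80)  # transducer
    for c in recording.channels:
        header += _edf_field("uV", 8)
    for v in pmin:
        header += _edf_field(f"{v:g}", 8)
    for v in pmax:
        header += _edf_field(f"{v:g}", 8)
    for _ in range(n_ch):
        header += _edf_field(str(dmin), 8)
    for _ in range(n_ch):
        header += _edf_field(str(dmax), 8)
    for _ in range(n_ch):
        header += _edf_field("", 80)  # prefiltering
    for _ in range(n_ch):
        header += _edf_field(str(spr), 8)
    for _ in range(n_ch):
        header += _edf_field("", 32)  # reserved

    # pad to a whole number of records with the channel minimum (digital dmin)
    padded = np.full((n_ch, n_records * spr), np.nan)
    padded[:, : recording.n_samples] = data
    for i in range(n_ch):
        padded[i, recording.n_samples:] = pmin[i]
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((padded - pmin[:, None]) * scale[:, None] + dmin)
    if np.any(digital < dmin) or np.any(digital > dmax):
        raise ValueError("signal exceeds the representable EDF range")
    digital = digital.astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            sl = slice(r * spr, (r + 1) * spr)
            fh.write(digital[:, sl].tobytes())

    sidecar = {
        "n_samples": recording.n_samples,
        "sfreq": sfreq,
        "blocks": [
            {
                "condition": b.condition,
                "repetition": b.repetition,
                "onset": b.onset,
                "duration": b.duration,
            }
            for b in recording.blocks
        ],
        "meta": _jsonable(recording.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# Reading (EDF and BrainVision via mne)
# ---------------------------------------------------------------------------

def _blocks_from_annotations(onsets, durations, descriptions) -> list[Block]:
    blocks = []
    for onset, dur, desc in zip(onsets, durations, descriptions):
        label = str(desc).strip().rsplit("/", 1)[-1]  # drop marker-type prefix
        m = _BLOCK_RE.match(label)
        if m is None:
            if "New Segment" not in str(desc):
                warnings.warn(
                    f"skipping unrecognised annotation label {desc!r}")
            continue
        blocks.append(Block(m.group(1), int(m.group(2)), float(onset), float(dur)))
    return blocks


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read an EDF or BrainVision recording into a :class:`Recording`.

    ``format`` is inferred from the extension when omitted (``.edf`` /
    ``.vhdr``).  Units are converted to microvolts.  Block annotations come
    from the JSON sidecar when present, otherwise from embedded EDF+ /
    BrainVision marker annotations with labels like ``OC_1``; a recording
    without any block annotation is returned with empty ``blocks`` and a
    warning.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {"edf": "EDF", "vhdr": "BrainVision"}.get(
            path.suffix.lstrip(".").lower(), ""
        )
    fmt = format.lower()
    if fmt == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif fmt == "brainvision":
        try:
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        except FileNotFoundError as exc:
            raise IOError(f"incomplete BrainVision triplet: {exc}") from exc
    else:
        raise ValueError(f"unsupported format {format!r}")

    data_uv = raw.get_data(units="uV")
    channels = [
        ChannelInfo(canonical_label(name), role_from_label(name))
        for name in raw.ch_names
    ]
    sfreq = float(raw.info["sfreq"])

    meta: dict = {}
    blocks: list[Block] = []
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        blocks = [
            Block(b["condition"], int(b["repetition"]), float(b["onset"]),
                  float(b["duration"]))
            for b in sidecar.get("blocks", [])
        ]
        meta = sidecar.get("meta", {})
        n_samples = sidecar.get("n_samples")
        if n_samples is not None:
            data_uv = data_uv[:, : int(n_samples)]
    elif len(raw.annotations) > 0:
        blocks = _blocks_from_annotations(
            raw.annotations.onset, raw.annotations.duration,
            raw.annotations.description,
        )
    if not blocks:
        warnings.warn(f"{path.name}: no condition-block annotations found")

    rec = Recording(sfreq=sfreq, channels=channels, data=data_uv,
                    blocks=blocks, meta=meta)
    rec.validate()
    return rec
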