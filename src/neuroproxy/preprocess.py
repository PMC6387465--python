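"""Band-pass filtering, overlapping epoching, and artifact rejection.

The filter is an 8th-order Butterworth band-pass (1-20 Hz by default),
realised as a high-pass/low-pass cascade and applied forward-backward
(zero phase) to the continuous signal before segmentation.  Epochs are
4-s windows advanced in 0.1-s steps within each condition block; a 120-s
block yields (120 - 4)/0.1 = 1160 epochs (no fencepost +1 — starts run
from 0 to block - epoch - step inclusive).

Two rejection rules flag whole epochs across all channels jointly:
amplitude (any sample strictly exceeding +-100 uV) and trend (least-squares
slope of any channel strictly exceeding 10 uV/s in magnitude).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .recordings_io import ChannelInfo, Recording

__all__ = [
    "FilterSpec",
    "EpochSet",
    "bandpass",
    "segment_epochs",
    "flag_amplitude",
    "flag_trend",
    "drop_flagged",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass: ``order``-th order high- and low-pass stages."""

    order: int = 8
    low_cut: float = 1.0
    high_cut: float = 20.0
    zero_phase: bool = True

    def validate(self, sfreq: float) -> None:
        nyq = sfreq / 2.0
        if not (0 < self.low_cut < self.high_cut):
            raise ValueError("need 0 < low_cut < high_cut")
        if self.high_cut >= nyq:
            raise ValueError(
                f"high_cut {self.high_cut} Hz >= Nyquist {nyq} Hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, sfreq: float) -> np.ndarray:
        self.validate(sfreq)
        hp = signal.butter(self.order, self.low_cut, btype="highpass",
                           fs=sfreq, output="sos")
        lp = signal.butter(self.order, self.high_cut, btype="lowpass",
                           fs=sfreq, output="sos")
        return np.vstack([hp, lp])


def bandpass(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Filter every channel of the continuous recording; annotations kept."""
    sos = spec.sos(recording.sfreq)
    out = recording.copy()
    if spec.zero_phase:
        out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    else:
        out.data = signal.sosfilt(sos, out.data, axis=1)
    return out


@dataclass
class EpochSet:
    """Windowed segments: ``data`` is epochs x channels x samples (uV).

    ``meta`` has one row per epoch (subject, condition, repetition,
    start_time); ``flags`` marks artifact epochs, ``reasons`` holds the
    rule names that fired per epoch.
    """

    sfreq: float
    channels: list[ChannelInfo]
    data: np.ndarray
    meta: pd.DataFrame
    flags: np.ndarray = field(default=None)
    reasons: list[set] = field(default=None)

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = np.zeros(len(self.data), dtype=bool)
        if self.reasons is None:
            self.reasons = [set() for _ in range(len(self.data))]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def epoch_length(self) -> float:
        return self.data.shape[2] / self.sfreq

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def copy(self) -> "EpochSet":
        return EpochSet(self.sfreq, list(self.channels), self.data,
                        self.meta.copy(), self.flags.copy(),
                        [set(r) for r in self.reasons])


def segment_epochs(recording: Recording, epoch_length: float = 4.0,
                   step: float = 0.1, subject=None) -> EpochSet:
    """Cut overlapping epochs from each annotated block.

    Epoch starts within a block are 0, step, 2*step, ...; the count equals
    ``floor((block - epoch) / step)`` (integer-sample arithmetic), so a
    120-s block at 4 s / 0.1 s gives 1160 epochs.  Blocks shorter than
    ``epoch_length + step`` yield no epochs, with a warning.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    fs = recording.sfreq
    n_ep = int(round(epoch_length * fs))
    n_step = int(round(step * fs))
    if n_step == 0:
        raise ValueError("step shorter than one sample")
    if subject is None:
        subject = recording.meta.get("subject")

    windows = []
    rows = []
    for b in recording.blocks:
        b_start = int(round(b.onset * fs))
        b_len = int(round(b.duration * fs))
        count = (b_len - n_ep) // n_step
        if count <= 0:
            warnings.warn(
                f"block {b.label} ({b.duration:g} s) too short for "
                f"{epoch_length:g}-s epochs at {step:g}-s step; skipped")
            continue
        for k in range(count):
            i0 = b_start + k * n_step
            windows.append(recording.data[:, i0:i0 + n_ep])
            rows.append({"subject": subject, "condition": b.condition,
                         "repetition": b.repetition,
                         "start_time": i0 / fs})
    data = (np.stack(windows) if windows
            else np.empty((0, recording.n_channels, n_ep)))
    meta = pd.DataFrame(rows, columns=["subject", "condition", "repetition",
                                       "start_time"])
    return EpochSet(sfreq=fs, channels=list(recording.channels), data=data,
                    meta=meta)


def flag_amplitude(epochs: EpochSet, limit: float = 100.0) -> EpochSet:
    """Flag epochs with any sample strictly above ``limit`` uV in magnitude."""
    if limit <= 0:
        raise ValueError("limit must be positive")
    out = epochs.copy()
    if out.n_epochs:
        hit = np.max(np.abs(out.data), axis=(1, 2)) > limit
        out.flags |= hit
        for i in np.nonzero(hit)[0]:
            out.reasons[i].add("amplitude")
    return out


def flag_trend(epochs: EpochSet, max_slope: float = 10.0) -> EpochSet:
    """Flag epochs whose least-squares linear trend on any channel exceeds
    ``max_slope`` uV/s in magnitude (strict inequality)."""
    if max_slope <= 0:
        raise ValueError("max_slope must be positive")
    out = epochs.copy()
    if out.n_epochs:
        n = out.data.shape[2]
        t = np.arange(n) / out.sfreq
        tc = t - t.mean()
        denom = np.dot(tc, tc)
        slopes = np.tensordot(out.data, tc, axes=([2], [0])) / denom
        hit = np.max(np.abs(slopes), axis=1) > max_slope
        out.flags |= hit
        for i in np.nonzero(hit)[0]:
            out.reasons[i].add("trend")
    return out


def drop_flagged(epochs: EpochSet) -> EpochSet:
    """Keep only unflagged epochs (metadata preserved, flags reset)."""
    keep = ~epochs.flags
    if epochs.n_epochs and not keep.any():
        subj = epochs.meta["subject"].iloc[0] if len(epochs.meta) else "?"
        raise ValueError(f"all epochs flagged as artifact (subject {subj})")
    return EpochSet(
        sfreq=epochs.sfreq,
        channels=list(epochs.channels),
        data=epochs.data[keep],
        meta=epochs.meta.loc[keep].reset_index(drop=True),
    )
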