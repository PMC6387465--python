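"""Power spectral density estimation and condition averaging.

Each artifact-free 4-s epoch becomes one Hann-windowed periodogram on a
0.25 Hz grid (4-s window at 250 Hz).  The estimate is window-power
corrected so white noise of variance sigma^2 integrates back to sigma^2,
and one-sided with the usual doubling of non-DC/non-Nyquist bins.

Averaging follows a two-level scheme: per-repetition means over that
repetition's surviving epochs, then the condition mean as the unweighted
mean of the repetition means (not of the pooled epochs).  dB conversion
uses 20*log10 and is display-only — every downstream computation (IAF,
correlation, classifier features) consumes linear PSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import windows

from .preprocess import EpochSet
from .recordings_io import ChannelInfo

__all__ = [
    "SpectrumSet",
    "epoch_psd",
    "repetition_mean",
    "condition_mean",
    "psd_to_db",
]


@dataclass
class SpectrumSet:
    """PSDs on a common frequency grid.

    ``values`` is epochs x channels x freqs for ``level='per_epoch'``
    (with ``meta`` rows matching epochs) or channels x freqs for averaged
    levels.  Units are uV^2/Hz unless ``unit`` says dB.
    """

    freqs: np.ndarray
    values: np.ndarray
    channels: list[ChannelInfo]
    level: str  # per_epoch | repetition_mean | condition_mean
    meta: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)
    unit: str = "uV^2/Hz"

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in spectra") from None

    def channel_profile(self, label: str) -> np.ndarray:
        """1-d spectrum of one channel (averaged levels only)."""
        if self.values.ndim != 2:
            raise ValueError("channel_profile needs an averaged SpectrumSet")
        return self.values[self.channel_index(label)]


def epoch_psd(epochs: EpochSet) -> SpectrumSet:
    """One Hann-windowed, one-sided periodogram per epoch and channel."""
    if epochs.n_epochs == 0:
        raise ValueError("no epochs to transform")
    n = epochs.data.shape[2]
    fs = epochs.sfreq
    w = windows.hann(n, sym=False)
    norm = 1.0 / (fs * np.dot(w, w))
    spec = np.fft.rfft(epochs.data * w, axis=2)
    psd = (spec.real ** 2 + spec.imag ** 2) * norm
    psd[..., 1:] *= 2.0
    if n % 2 == 0:  # undo doubling at Nyquist
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return SpectrumSet(freqs=freqs, values=psd,
                       channels=list(epochs.channels), level="per_epoch",
                       meta=epochs.meta.reset_index(drop=True))


def repetition_mean(spectra: SpectrumSet, condition: str,
                    repetition: int) -> SpectrumSet:
    """Mean PSD over the epochs of one (condition, repetition) block."""
    if spectra.level != "per_epoch":
        raise ValueError("repetition_mean needs per-epoch spectra")
    mask = ((spectra.meta["condition"] == condition)
            & (spectra.meta["repetition"] == repetition)).to_numpy()
    if not mask.any():
        raise ValueError(f"no epochs for {condition}_{repetition}")
    return SpectrumSet(
        freqs=spectra.freqs,
        values=spectra.values[mask].mean(axis=0),
        channels=list(spectra.channels),
        level="repetition_mean",
        provenance={"condition": condition, "repetition": repetition,
                    "n_epochs": int(mask.sum())},
    )


def condition_mean(spectra: SpectrumSet, condition: str,
                   n_repetitions: int = 4) -> SpectrumSet:
    """Unweighted mean of the per-repetition mean PSDs of one condition."""
    if spectra.level != "per_epoch":
        raise ValueError("condition_mean needs per-epoch spectra")
    present = sorted(
        spectra.meta.loc[spectra.meta["condition"] == condition,
                         "repetition"].unique())
    if not present:
        raise ValueError(f"no repetitions present for condition {condition}")
    if len(present) < n_repetitions:
        warnings.warn(
            f"condition {condition}: only {len(present)} of "
            f"{n_repetitions} repetitions present")
    reps = [repetition_mean(spectra, condition, r) for r in present]
    return SpectrumSet(
        freqs=spectra.freqs,
        values=np.mean([r.values for r in reps], axis=0),
        channels=list(spectra.channels),
        level="condition_mean",
        provenance={"condition": condition, "repetitions": list(present),
                    "n_epochs": [r.provenance["n_epochs"] for r in reps]},
    )


def psd_to_db(spectra: SpectrumSet, floor: float | None = None) -> SpectrumSet:
    """Display normalisation ``20 * log10(PSD)``.

    Zero or negative PSD raises unless an explicit epsilon ``floor`` is
    given.  The result is for plotting/reporting only.
    """
    vals = np.asarray(spectra.values, dtype=float)
    if floor is not None:
        vals = np.maximum(vals, floor)
    if np.any(vals <= 0):
        raise ValueError("PSD must be strictly positive for dB conversion "
                         "(pass floor= to clip)")
    return SpectrumSet(
        freqs=spectra.freqs, values=20.0 * np.log10(vals),
        channels=list(spectra.channels), level=spectra.level,
        meta=None if spectra.meta is None else spectra.meta.copy(),
        provenance=dict(spectra.provenance), unit="dB",
    )
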