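"""Individual alpha frequency (IAF) estimation and IAF-anchored bands.

The IAF is located inside the traditional alpha search window
(7.5-12.5 Hz) on a condition-mean spectrum, by either of two estimators:

* **peak** — the frequency bin with the largest power in the window (grid-
  valued, so two channels can agree *exactly*);
* **gravity** — the power-weighted mean frequency
  ``sum(a(f) * f) / sum(a(f))`` over the window, preferred when the
  spectrum shows multiple alpha peaks.

The five analysis bands are anchored to the IAF:
Delta (0, IAF-6), Theta (IAF-6, IAF-2), Alpha (IAF-2, IAF+2),
Beta (IAF+2, IAF+16), Gamma (IAF+16, IAF+25).  Band membership of the
0.25 Hz bins uses half-open intervals [f1, f2), intersected with the
1-20 Hz analysis range of the band-pass — the convention under which the
4-Hz Theta and Alpha bands contain exactly 16 bins each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectral import SpectrumSet

__all__ = [
    "AlphaSearchRange",
    "IAFEstimate",
    "BandTable",
    "BAND_NAMES",
    "iaf_peak",
    "iaf_gravity",
    "estimate_iaf",
    "define_bands",
    "band_bins",
]

BAND_NAMES = ("Delta", "Theta", "Alpha", "Beta", "Gamma")


@dataclass(frozen=True)
class AlphaSearchRange:
    f1: float = 7.5
    f2: float = 12.5

    def __post_init__(self):
        if not self.f1 < self.f2:
            raise ValueError("need f1 < f2")


@dataclass(frozen=True)
class IAFEstimate:
    value: float  # Hz
    method: str  # "peak" | "gravity"
    n_local_maxima: int
    channel: str | None = None
    condition: str | None = None
    degenerate: bool = False  # no interior local maximum in the window


@dataclass(frozen=True)
class BandTable:
    """IAF-anchored (f1, f2) edges for the five bands."""

    iaf: float
    Delta: tuple[float, float]
    Theta: tuple[float, float]
    Alpha: tuple[float, float]
    Beta: tuple[float, float]
    Gamma: tuple[float, float]

    def __getitem__(self, name: str) -> tuple[float, float]:
        if name not in BAND_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def items(self):
        return [(n, getattr(self, n)) for n in BAND_NAMES]


def _window(freqs: np.ndarray, profile: np.ndarray,
            rng: AlphaSearchRange) -> tuple[np.ndarray, np.ndarray]:
    mask = (freqs >= rng.f1 - 1e-9) & (freqs <= rng.f2 + 1e-9)
    if mask.sum() < 2:
        raise ValueError("search range covers fewer than 2 bins")
    return freqs[mask], np.asarray(profile, dtype=float)[mask]


def _count_local_maxima(p: np.ndarray) -> int:
    if p.size < 3:
        return 0
    interior = p[1:-1]
    return int(np.sum((interior > p[:-2]) & (interior > p[2:])))


def _profile(spectrum, channel: str | None):
    """Accept a SpectrumSet (+channel) or a bare (freqs, values) pair."""
    if isinstance(spectrum, SpectrumSet):
        if channel is None:
            if spectrum.values.ndim == 2 and len(spectrum.channels) == 1:
                return spectrum.freqs, spectrum.values[0], spectrum
            raise ValueError("channel label required for multichannel spectra")
        return spectrum.freqs, spectrum.channel_profile(channel), spectrum
    freqs, values = spectrum
    return np.asarray(freqs, float), np.asarray(values, float), None


def iaf_peak(spectrum, rng: AlphaSearchRange = AlphaSearchRange(),
             channel: str | None = None, smooth: bool = False) -> IAFEstimate:
    """Peak-frequency estimator: the largest-power bin inside the window.

    A spectrum with no interior local maximum (e.g. a monotone 1/f slope)
    is flagged ``degenerate`` — use the gravity estimator instead.  Ties
    between equal maximal bins resolve to the lowest frequency and are
    reported via ``n_local_maxima``.  ``smooth`` applies a 3-bin moving
    average before peak detection (off by default).
    """
    freqs, values, spec = _profile(spectrum, channel)
    f, p = _window(freqs, values, rng)
    if smooth and p.size >= 3:
        p = np.convolve(p, np.ones(3) / 3.0, mode="same")
        p[0], p[-1] = p[1], p[-2]  # damp edge bias of the short windows
    n_max = _count_local_maxima(p)
    idx = int(np.argmax(p))
    degenerate = n_max == 0
    if degenerate:
        warnings.warn("no interior local maximum in the alpha window; "
                      "peak estimate is degenerate — prefer gravity")
    cond = spec.provenance.get("condition") if spec is not None else None
    return IAFEstimate(value=float(f[idx]), method="peak",
                       n_local_maxima=n_max, channel=channel,
                       condition=cond, degenerate=degenerate)


def iaf_gravity(spectrum, rng: AlphaSearchRange = AlphaSearchRange(),
                channel: str | None = None) -> IAFEstimate:
    """Gravity (mean-frequency) estimator over the alpha window."""
    freqs, values, spec = _profile(spectrum, channel)
    f, p = _window(freqs, values, rng)
    total = float(np.sum(p))
    if total <= 0:
        raise ValueError("zero alpha power: gravity frequency undefined")
    cond = spec.provenance.get("condition") if spec is not None else None
    return IAFEstimate(value=float(np.dot(p, f) / total), method="gravity",
                       n_local_maxima=_count_local_maxima(p),
                       channel=channel, condition=cond)


def estimate_iaf(spectrum, rng: AlphaSearchRange = AlphaSearchRange(),
                 policy: str = "auto",
                 channel: str | None = None) -> IAFEstimate:
    """Combined policy: peak for a unique interior maximum, gravity for
    multiple alpha peaks or a degenerate (peakless) window.

    ``policy`` may force ``"peak"`` or ``"gravity"``.
    """
    if policy == "peak":
        return iaf_peak(spectrum, rng, channel)
    if policy == "gravity":
        return iaf_gravity(spectrum, rng, channel)
    if policy != "auto":
        raise ValueError(f"unknown policy {policy!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        peak = iaf_peak(spectrum, rng, channel)
    if peak.n_local_maxima == 1 and not peak.degenerate:
        return peak
    return iaf_gravity(spectrum, rng, channel)


def define_bands(iaf: IAFEstimate | float) -> BandTable:
    """IAF-anchored band edges (Hz); requires IAF > 6 so Delta is non-empty."""
    value = iaf.value if isinstance(iaf, IAFEstimate) else float(iaf)
    if value <= 6.0:
        raise ValueError(f"IAF {value} Hz <= 6 Hz leaves an empty Delta band")
    return BandTable(
        iaf=value,
        Delta=(0.0, value - 6.0),
        Theta=(value - 6.0, value - 2.0),
        Alpha=(value - 2.0, value + 2.0),
        Beta=(value + 2.0, value + 16.0),
        Gamma=(value + 16.0, value + 25.0),
    )


def band_bins(band: tuple[float, float], resolution: float = 0.25,
              analysis_range: tuple[float, float] = (1.0, 20.0)) -> np.ndarray:
    """Frequency bins of a band: half-open [f1, f2) at ``resolution``
    granularity, intersected with the (half-open) analysis range.

    A 4-Hz band fully inside the range yields 16 bins at 0.25 Hz.
    """
    f1, f2 = band
    if not f1 < f2:
        raise ValueError("need f1 < f2")
    lo = max(f1, analysis_range[0])
    hi = min(f2, analysis_range[1])
    start = int(np.ceil(lo / resolution - 1e-9))
    stop = int(np.ceil(hi / resolution - 1e-9))  # exclusive
    if stop <= start:
        warnings.warn(f"band {band} has no bins inside analysis range "
                      f"{analysis_range}")
        return np.empty(0)
    return np.arange(start, stop) * resolution
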