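"""Synthetic cohorts of EEG + non-cerebral ("noEEG") recordings.

Each simulated subject alternates eyes-closed (OC) and eyes-open (OA)
blocks.  Band-limited stochastic oscillators — an alpha oscillator at the
subject's individual alpha frequency (IAF), plus theta/delta/beta
components — are mixed into the scalp channels over 1/f background noise.
The alpha oscillator is strong in OC and attenuated in OA (posterior
dominance), while theta/delta/beta are relatively stronger in OA, so every
IAF-anchored band carries an eyes-state signature.  A scalar coupling
coefficient per noEEG channel propagates an attenuated copy of the
posterior source mixture onto neck/wrist electrodes (instantaneous volume
conduction), on top of their own background noise.

Oscillators are amplitude-modulated sinusoids with a slow random envelope,
not pure tones, so spectral peaks have realistic nonzero width.  Subject IAF
values are quantized to the 0.25 Hz analysis grid.

Artifact transients (blink-like frontal deflections, broadband EMG bursts,
periodic ECG-like spikes on neck channels) can be injected at configured
rates with ground-truth event logs, to exercise downstream rejection rules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recordings_io import (
    Block,
    ChannelInfo,
    Recording,
    default_montage,
    mini_montage,
)

__all__ = [
    "SimulationConfig",
    "generate_subject",
    "generate_cohort",
    "inject_artifacts",
    "DEFAULT_COUPLING",
]

#: Volume-conduction coefficients of the posterior source mixture onto the
#: noEEG channels.  The channels that later serve as classifier features are
#: coupled; the remaining electrodes see none of the cerebral sources.
DEFAULT_COUPLING: dict[str, float] = {
    "Neck2": 0.65, "Neck4": 0.7, "Neck5": 0.6, "Neck6": 0.6,
    "WrL2": 0.45, "WrR1": 0.45, "WrR2": 0.5, "WrR4": 0.4,
}

# Relative weight of each source on the scalp channels, by channel-group
# prefix.  Alpha is posterior-dominant; theta/delta are fronto-central;
# beta is central.
_ALPHA_W = {"O": 1.0, "PO": 0.9, "P": 0.8, "CP": 0.65, "C": 0.5, "F": 0.35,
            "AF": 0.25, "Fp": 0.2}
_THETA_W = {"Fp": 0.8, "AF": 0.9, "F": 1.0, "C": 0.9, "CP": 0.7, "P": 0.6,
            "PO": 0.5, "O": 0.45}
_DELTA_W = {"Fp": 1.0, "AF": 0.9, "F": 0.85, "C": 0.7, "CP": 0.6, "P": 0.55,
            "PO": 0.5, "O": 0.45}
_BETA_W = {"Fp": 0.5, "AF": 0.55, "F": 0.7, "C": 1.0, "CP": 0.9, "P": 0.7,
           "PO": 0.55, "O": 0.5}

_FRONTAL = ["Fp1", "Fp2", "AF3", "AFz", "AF4"]


@dataclass
class SimulationConfig:
    """Cohort generator parameters.

    Amplitudes are RMS microvolts of the band oscillators per condition;
    ``subject_iaf`` is either a fixed Hz value or an ``(lo, hi)`` range
    sampled uniformly and quantized to 0.25 Hz.  ``coupling`` maps noEEG
    channel labels to volume-conduction coefficients in [0, 1]; unlisted
    channels are uncoupled.  Artifact rates are events per minute.
    """

    n_subjects: int = 12
    sampling_rate: float = 250.0
    block_length: float = 120.0
    n_repetitions: int = 4
    subject_iaf: float | tuple[float, float] = (8.0, 12.0)
    alpha_amp_oc: float = 8.0
    alpha_amp_oa: float = 1.0
    theta_amp_oc: float = 1.0
    theta_amp_oa: float = 3.2
    delta_amp_oc: float = 1.2
    delta_amp_oa: float = 3.6
    beta_amp_oc: float = 0.8
    beta_amp_oa: float = 2.6
    background_exponent: float = 1.0
    background_scale: float = 3.0
    noeeg_background_scale: float = 2.0
    coupling: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING))
    blink_rate: float = 0.25
    blink_amp: float = 250.0
    emg_rate: float = 0.2
    emg_amp: float = 300.0
    ecg_rate: float = 60.0
    ecg_amp: float = 25.0
    montage: str = "full"  # "full" (27+16) or "mini" (fast tests)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sampling_rate <= 0 or self.block_length <= 0:
            raise ValueError("sampling_rate and block_length must be positive")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        amps = [self.alpha_amp_oc, self.alpha_amp_oa, self.theta_amp_oc,
                self.theta_amp_oa, self.delta_amp_oc, self.delta_amp_oa,
                self.beta_amp_oc, self.beta_amp_oa, self.background_scale,
                self.noeeg_background_scale, self.blink_amp, self.emg_amp,
                self.ecg_amp]
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be non-negative")
        if any(r < 0 for r in (self.blink_rate, self.emg_rate, self.ecg_rate)):
            raise ValueError("artifact rates must be non-negative")
        for ch, c in self.coupling.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling[{ch!r}]={c} outside [0, 1]")
        lo, hi = self._iaf_bounds()
        if not (lo <= hi):
            raise ValueError("subject_iaf range inverted")
        # highest simulated frequency: beta oscillator below 20 Hz
        if self.sampling_rate <= 2 * 20.0:
            raise ValueError("sampling rate must exceed twice the highest "
                             "simulated frequency")
        if self.theta_amp_oa < self.theta_amp_oc:
            warnings.warn("theta_amp_oa < theta_amp_oc: eyes-open theta is "
                          "expected to dominate")

    def _iaf_bounds(self) -> tuple[float, float]:
        if isinstance(self.subject_iaf, (int, float)):
            return float(self.subject_iaf), float(self.subject_iaf)
        lo, hi = self.subject_iaf
        return float(lo), float(hi)

    def montage_channels(self) -> list[ChannelInfo]:
        if self.montage == "full":
            return default_montage()
        if self.montage == "mini":
            return mini_montage()
        raise ValueError(f"unknown montage {self.montage!r}")


def _subject_rng(config: SimulationConfig, subject_index: int,
                 stream: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=int(config.seed), spawn_key=(subject_index, stream))
    return np.random.default_rng(ss)


def _draw_iaf(config: SimulationConfig, rng: np.random.Generator) -> float:
    lo, hi = config._iaf_bounds()
    if hi == lo:
        return round(lo / 0.25) * 0.25
    grid = np.arange(math.ceil(lo / 0.25), math.floor(hi / 0.25) + 1) * 0.25
    return float(rng.choice(grid))


def _envelope(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Slow positive random amplitude envelope with ~0.2 Hz bandwidth."""
    z = rng.standard_normal(n)
    sos = signal.butter(2, 0.2, btype="lowpass", fs=fs, output="sos")
    slow = signal.sosfiltfilt(sos, z)
    slow = slow / (np.std(slow) + 1e-12)
    return np.clip(1.0 + 0.5 * slow, 0.05, None)


def _oscillator(n: int, fs: float, f0: float, amp: float,
                rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated sinusoid at ``f0`` with RMS ``amp`` (uV)."""
    if amp == 0.0:
        # keep the rng stream aligned across conditions
        rng.uniform()
        _envelope(n, fs, rng)
        return np.zeros(n)
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * f0 * t + phase)
    env = _envelope(n, fs, rng)
    s = carrier * env
    return s * (amp / (np.std(s) + 1e-12))


def _one_over_f(n: int, fs: float, exponent: float, scale: float,
                rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^exponent noise with RMS ``scale`` (uV)."""
    white = rng.standard_normal(n)
    if scale == 0.0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x * (scale / (np.std(x) + 1e-12))


def _group_weight(label: str, table: dict[str, float]) -> float:
    for prefix in ("Fp", "AF", "CP", "PO", "F", "C", "P", "O"):
        if label.startswith(prefix):
            return table[prefix]
    return 0.0


def generate_subject(config: SimulationConfig,
                     subject_index: int = 0) -> Recording:
    """Simulate one subject's continuous recording with annotated blocks.

    The block order is a seeded random permutation of ``n_repetitions`` OC
    plus ``n_repetitions`` OA blocks.  Ground truth (IAF, block order,
    subject index) lands in ``Recording.meta``.
    """
    config.validate()
    if subject_index >= config.n_subjects:
        raise ValueError("subject_index out of range")
    rng = _subject_rng(config, subject_index)
    fs = config.sampling_rate
    iaf = _draw_iaf(config, rng)

    # source centre frequencies anchored to the subject's IAF-defined bands
    f_alpha = iaf
    f_theta = iaf - 4.0                       # mid Theta band (IAF-6, IAF-2)
    f_delta = (1.0 + max(iaf - 6.0, 2.0)) / 2  # mid in-range Delta band
    f_beta = min(iaf + 6.0, 18.0)             # within Beta band and < 20 Hz

    conditions = ["OC"] * config.n_repetitions + ["OA"] * config.n_repetitions
    order = rng.permutation(len(conditions))
    n_block = int(round(config.block_length * fs))
    channels = config.montage_channels()
    labels = [c.label for c in channels]
    n_total = n_block * len(conditions)
    data = np.zeros((len(channels), n_total))

    blocks: list[Block] = []
    rep_counter = {"OC": 0, "OA": 0}
    amps = {
        "OC": {"alpha": config.alpha_amp_oc, "theta": config.theta_amp_oc,
               "delta": config.delta_amp_oc, "beta": config.beta_amp_oc},
        "OA": {"alpha": config.alpha_amp_oa, "theta": config.theta_amp_oa,
               "delta": config.delta_amp_oa, "beta": config.beta_amp_oa},
    }
    weights = {"alpha": _ALPHA_W, "theta": _THETA_W, "delta": _DELTA_W,
               "beta": _BETA_W}
    freqs = {"alpha": f_alpha, "theta": f_theta, "delta": f_delta,
             "beta": f_beta}

    for k, pos in enumerate(order):
        cond = conditions[pos]
        rep_counter[cond] += 1
        onset = k * config.block_length
        blocks.append(Block(cond, rep_counter[cond], onset,
                            config.block_length))
        sl = slice(k * n_block, (k + 1) * n_block)

        sources = {name: _oscillator(n_block, fs, freqs[name],
                                     amps[cond][name], rng)
                   for name in ("alpha", "theta", "delta", "beta")}
        # posterior reference mixture seen by coupled noEEG channels
        ref = sum(_group_weight("Oz", weights[name]) * sources[name]
                  for name in sources)
        for i, ch in enumerate(channels):
            if ch.role == "EEG":
                mix = sum(_group_weight(ch.label, weights[name]) * sources[name]
                          for name in sources)
                noise = _one_over_f(n_block, fs, config.background_exponent,
                                    config.background_scale, rng)
                data[i, sl] = mix + noise
            else:
                c = config.coupling.get(ch.label, 0.0)
                noise = _one_over_f(n_block, fs, config.background_exponent,
                                    config.noeeg_background_scale, rng)
                data[i, sl] = c * ref + noise

    rec = Recording(
        sfreq=fs, channels=channels, data=data, blocks=blocks,
        meta={
            "subject": subject_index,
            "true_iaf": iaf,
            "block_order": [conditions[p] for p in order],
            "coupling": {ch.label: config.coupling.get(ch.label, 0.0)
                         for ch in channels if ch.role != "EEG"},
        },
    )
    rec.validate()
    return rec


def generate_cohort(config: SimulationConfig,
                    with_artifacts: bool = True) -> list[Recording]:
    """Simulate the whole cohort; per-subject seeds derive from the master seed.

    Ground-truth IAF values and (when ``with_artifacts``) injected event
    logs are recorded in each :class:`Recording`'s ``meta``.
    """
    config.validate()
    recordings = []
    any_rate = (config.blink_rate > 0 or config.emg_rate > 0
                or config.ecg_rate > 0)
    for s in range(config.n_subjects):
        rec = generate_subject(config, s)
        if with_artifacts and any_rate:
            rec, events = inject_artifacts(rec, config,
                                           rng=_subject_rng(config, s, 1))
            rec.meta["artifact_events"] = events
        recordings.append(rec)
    return recordings


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

def _event_times(rate_per_min: float, duration: float,
                 rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate_per_min * duration / 60.0)
    return np.sort(rng.uniform(0.0, duration, size=n))


def inject_artifacts(recording: Recording, config: SimulationConfig,
                     rng: np.random.Generator | None = None,
                     seed: int | None = None):
    """Add blink / EMG / ECG transients; returns ``(recording, events)``.

    Blinks are ~0.3 s low-frequency deflections on the frontal channels;
    EMG bursts are 0.3 s broadband transients on one random channel; ECG
    beats are periodic sharp spikes on the neck channels.  With all rates
    zero the recording is returned unchanged (a copy) with an empty log.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    out = recording.copy()
    events: list[dict] = []
    fs = out.sfreq
    n = out.n_samples
    duration = out.duration
    labels = out.labels

    frontal = [l for l in labels if l in _FRONTAL] or \
        [l for l in labels if l == "Fz"]
    neck = [l for l in labels if l.startswith("Neck")]

    # blinks: Gaussian bump, sigma 80 ms
    for t0 in _event_times(config.blink_rate, duration, rng):
        i0 = int(t0 * fs)
        width = int(0.3 * fs)
        idx = np.arange(max(0, i0 - width), min(n, i0 + width))
        bump = config.blink_amp * np.exp(-0.5 * ((idx - i0) / (0.08 * fs)) ** 2)
        for l in frontal:
            out.data[out.channel_index(l), idx] += bump
        events.append({"kind": "blink", "time": float(t0), "duration": 0.6,
                       "channels": list(frontal)})

    # EMG bursts: 0.3 s of high-pass-ish white noise on one channel
    for t0 in _event_times(config.emg_rate, duration, rng):
        ch = labels[rng.integers(len(labels))]
        i0 = int(t0 * fs)
        idx = np.arange(i0, min(n, i0 + int(0.3 * fs)))
        if idx.size == 0:
            continue
        burst = rng.standard_normal(idx.size)
        burst *= config.emg_amp / (np.max(np.abs(burst)) + 1e-12)
        out.data[out.channel_index(ch), idx] += burst
        events.append({"kind": "emg", "time": float(t0), "duration": 0.3,
                       "channels": [ch]})

    # ECG: quasi-periodic biphasic spikes on neck channels
    if config.ecg_rate > 0 and neck:
        period = 60.0 / config.ecg_rate
        t0 = rng.uniform(0, period)
        beats = []
        while t0 < duration:
            beats.append(t0)
            t0 += period * rng.uniform(0.95, 1.05)
        width = int(0.04 * fs)
        for tb in beats:
            i0 = int(tb * fs)
            idx = np.arange(max(0, i0 - width), min(n, i0 + width))
            spike = config.ecg_amp * np.exp(
                -0.5 * ((idx - i0) / (0.012 * fs)) ** 2)
            spike -= 0.3 * config.ecg_amp * np.exp(
                -0.5 * ((idx - i0 - 0.02 * fs) / (0.02 * fs)) ** 2)
            for l in neck:
                out.data[out.channel_index(l), idx] += spike
        if beats:
            events.append({"kind": "ecg", "time": float(beats[0]),
                           "duration": duration, "channels": list(neck),
                           "n_beats": len(beats)})

    return out, events
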