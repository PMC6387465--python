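"""EEG-noEEG alpha-profile correlation, common pattern, IAF-difference map.

For each subject, the mean eyes-closed (OC) spectra of an EEG channel and
a noEEG channel are compared bin-by-bin across the fixed 7.5-12.5 Hz alpha
window with Pearson's R (two-sided p from the exact t transform).  A
channel couple enters the *common pattern* only if every subject shows a
positive (R > 0) and significant (p < 0.05) correlation — a single failing
subject excludes the couple.  No multiple-testing correction is applied to
the 27 x 16 couple grid (optional FDR switch available).

For the surviving couples the per-subject IAF difference
``d = IAF_EEG - IAF_noEEG`` is averaged across subjects and categorised:
``equal`` (d = 0), ``eeg_higher`` (0 < d <= 0.25), ``eeg_lower``
(-0.25 <= d < 0), ``out_of_range`` (|d| > 0.25).  Zero-difference couples
are the candidates for classifier feature channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .iafband import AlphaSearchRange, IAFEstimate
from .spectral import SpectrumSet

__all__ = [
    "CoupleCorrelation",
    "alpha_profile_correlation",
    "correlate_channels",
    "common_pattern",
    "iaf_difference_map",
    "categorize_difference",
]


@dataclass(frozen=True)
class CoupleCorrelation:
    eeg_channel: str
    noeeg_channel: str
    r: float
    p: float
    n_points: int
    subject: object = None


def alpha_profile_correlation(freqs, profile_eeg, profile_noeeg,
                              rng: AlphaSearchRange = AlphaSearchRange(),
                              eeg_channel: str = "", noeeg_channel: str = "",
                              subject=None) -> CoupleCorrelation:
    """Pearson R between two mean-OC spectral profiles across alpha bins."""
    freqs = np.asarray(freqs, float)
    mask = (freqs >= rng.f1 - 1e-9) & (freqs <= rng.f2 + 1e-9)
    x = np.asarray(profile_eeg, float)[mask]
    y = np.asarray(profile_noeeg, float)[mask]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 alpha bins for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a spectral profile: R undefined")
    res = stats.pearsonr(x, y)
    return CoupleCorrelation(eeg_channel=eeg_channel,
                             noeeg_channel=noeeg_channel,
                             r=float(res.statistic), p=float(res.pvalue),
                             n_points=n, subject=subject)


def correlate_channels(mean_oc: SpectrumSet, eeg_channels: list[str],
                       noeeg_channels: list[str],
                       rng: AlphaSearchRange = AlphaSearchRange(),
                       subject=None) -> list[CoupleCorrelation]:
    """All EEG x noEEG couple correlations for one subject's mean-OC spectra."""
    out = []
    for e in eeg_channels:
        pe = mean_oc.channel_profile(e)
        for ne in noeeg_channels:
            pn = mean_oc.channel_profile(ne)
            out.append(alpha_profile_correlation(
                mean_oc.freqs, pe, pn, rng,
                eeg_channel=e, noeeg_channel=ne, subject=subject))
    return out


def _fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        prev = min(prev, p[i] * m / (rank_idx + 1))
        adj[i] = prev
    return adj


def common_pattern(per_subject: dict[object, list[CoupleCorrelation]],
                   alpha: float = 0.05,
                   fdr: bool = False) -> set[tuple[str, str]]:
    """Couples with R > 0 and p < alpha in *every* subject.

    All subjects must have been evaluated on the same couple set.  With
    ``fdr=True`` p-values are Benjamini-Hochberg adjusted within subject
    before thresholding (off by default — the raw rule is the reference
    behaviour).
    """
    if not per_subject:
        return set()
    couple_sets = {}
    for subj, results in per_subject.items():
        couples = {(c.eeg_channel, c.noeeg_channel) for c in results}
        couple_sets[subj] = couples
    ref = next(iter(couple_sets.values()))
    for subj, couples in couple_sets.items():
        if couples != ref:
            raise ValueError(f"subject {subj!r} evaluated on a different "
                             "couple set")
    pattern = set(ref)
    for results in per_subject.values():
        pvals = np.array([c.p for c in results])
        if fdr:
            pvals = _fdr(pvals)
        passing = {(c.eeg_channel, c.noeeg_channel)
                   for c, p in zip(results, pvals)
                   if c.r > 0 and p < alpha}
        pattern &= passing
    return pattern


def categorize_difference(d: float, tol: float = 1e-9) -> str:
    if abs(d) <= tol:
        return "equal"
    if 0 < d <= 0.25 + tol:
        return "eeg_higher"
    if -0.25 - tol <= d < 0:
        return "eeg_lower"
    return "out_of_range"


def iaf_difference_map(pattern: set[tuple[str, str]],
                       iaf_by_channel: dict[object, dict[str, IAFEstimate]],
                       ) -> pd.DataFrame:
    """Per-couple IAF differences for the common-pattern couples.

    ``iaf_by_channel`` maps subject -> channel label -> IAF estimate.
    Returns one row per couple with the per-subject differences, their
    cross-subject mean, and the category of the mean; couples in the
    ``equal`` category are the feature-channel candidates.
    """
    rows = []
    subjects = sorted(iaf_by_channel, key=str)
    for eeg_ch, noeeg_ch in sorted(pattern):
        ds = []
        for subj in subjects:
            table = iaf_by_channel[subj]
            for ch in (eeg_ch, noeeg_ch):
                if ch not in table:
                    raise KeyError(
                        f"missing IAF for channel {ch!r}, subject {subj!r}")
            e, n = table[eeg_ch], table[noeeg_ch]
            ev = e.value if isinstance(e, IAFEstimate) else float(e)
            nv = n.value if isinstance(n, IAFEstimate) else float(n)
            ds.append(ev - nv)
        mean_d = float(np.mean(ds))
        rows.append({
            "eeg_channel": eeg_ch,
            "noeeg_channel": noeeg_ch,
            "mean_difference": mean_d,
            "category": categorize_difference(mean_d),
            "per_subject": ds,
        })
    return pd.DataFrame(
        rows, columns=["eeg_channel", "noeeg_channel", "mean_difference",
                       "category", "per_subject"])
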