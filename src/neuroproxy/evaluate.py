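"""Repetition-paired cross-validation, AUC/ACC metrics, and band summaries.

Cross-validation pairs the i-th eyes-closed and eyes-open repetitions:
each (OC_i, OA_i) couple trains the classifier once, and each of the
remaining couples is scored *separately*, giving 4 folds x 3 test couples
= 12 (AUC, ACC) evaluations per subject, band, and feature set, which are
then averaged.

AUC uses the rank (Mann-Whitney) formulation with midrank tie handling —
the probability that a random OC epoch outscores a random OA epoch.
Accuracy thresholds the 0/1-coded discriminant output at 0.5.  EEG vs
noEEG comparisons use two-tailed paired t-tests on per-subject
band-averaged metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .iafband import BandTable, band_bins
from .spectral import SpectrumSet
from .swlda import FeatureMatrix, SWLDAConfig, SWLDAModel, discriminant_scores, fit_swlda

__all__ = [
    "Fold",
    "make_folds",
    "compute_auc",
    "compute_acc",
    "build_feature_matrix",
    "run_band_cv",
    "paired_ttest",
    "EvaluationSummary",
    "summarize",
]


@dataclass(frozen=True)
class Fold:
    train_repetition: int
    test_repetitions: tuple[int, ...]


def make_folds(repetitions: list[int]) -> list[Fold]:
    """One fold per (OC_i, OA_i) couple used for training; the rest test."""
    reps = sorted(set(repetitions))
    if len(reps) < 2:
        raise ValueError("need at least 2 repetition couples for "
                         "cross-validation")
    return [Fold(r, tuple(t for t in reps if t != r)) for r in reps]


def compute_auc(scores, labels) -> float:
    """Rank-based AUC (Wilcoxon/Mann-Whitney statistic, midrank ties)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes in the test set")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def compute_acc(scores, labels, threshold: float = 0.5) -> float:
    """Fraction of epochs whose thresholded score matches the OC/OA label."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty test set")
    pred = (scores >= threshold).astype(int)
    return float(np.mean(pred == labels))


def build_feature_matrix(spectra: SpectrumSet, channels: list[str],
                         band: tuple[float, float],
                         resolution: float = 0.25,
                         analysis_range: tuple[float, float] = (1.0, 20.0),
                         mask=None) -> FeatureMatrix:
    """Linear-PSD features (channel x band-bin columns) from per-epoch spectra.

    Feature columns are named ``<channel>@<freq>`` so models align by name
    across folds.  ``mask`` selects a subset of epochs.
    """
    if spectra.level != "per_epoch":
        raise ValueError("feature building needs per-epoch spectra")
    bins = band_bins(band, resolution, analysis_range)
    if bins.size == 0:
        raise ValueError(f"band {band} has no bins in the analysis range")
    bin_idx = np.searchsorted(spectra.freqs, bins - 1e-9)
    ch_idx = [spectra.channel_index(c) for c in channels]
    vals = spectra.values if mask is None else spectra.values[mask]
    block = vals[:, ch_idx][:, :, bin_idx]  # epochs x ch x bins
    X = block.reshape(block.shape[0], -1)
    names = [f"{c}@{f:.2f}" for c in channels for f in bins]
    meta = spectra.meta if mask is None else spectra.meta.loc[mask]
    y = (meta["condition"] == "OC").to_numpy().astype(float)
    return FeatureMatrix(X=X, y=y, feature_names=names)


def run_band_cv(spectra: SpectrumSet, band: tuple[float, float],
                channels: list[str], scheme: list[Fold],
                config: SWLDAConfig = SWLDAConfig(),
                resolution: float = 0.25,
                analysis_range: tuple[float, float] = (1.0, 20.0),
                pool_test: bool = False) -> pd.DataFrame:
    """Cross-validated OC/OA discrimination within one frequency band.

    Returns one row per (fold, test couple) with AUC, ACC and the selected
    model size.  ``pool_test=True`` instead scores each fold's test couples
    jointly (one row per fold).
    """
    meta = spectra.meta
    rows = []
    for fold in scheme:
        train_mask = (meta["repetition"] == fold.train_repetition).to_numpy()
        fm_train = build_feature_matrix(spectra, channels, band, resolution,
                                        analysis_range, mask=train_mask)
        model = fit_swlda(fm_train, config)
        test_groups = ([fold.test_repetitions] if pool_test
                       else [(r,) for r in fold.test_repetitions])
        for group in test_groups:
            test_mask = meta["repetition"].isin(group).to_numpy()
            fm_test = build_feature_matrix(spectra, channels, band,
                                           resolution, analysis_range,
                                           mask=test_mask)
            s = discriminant_scores(model, fm_test)
            rows.append({
                "train_repetition": fold.train_repetition,
                "test_repetitions": group,
                "auc": compute_auc(s, fm_test.y),
                "acc": compute_acc(s, fm_test.y),
                "n_features": model.n_features,
            })
    return pd.DataFrame(rows)


def paired_ttest(values_a, values_b) -> tuple[float, float]:
    """Two-tailed paired t-test on per-subject metric vectors.

    Identical vectors return ``(0.0, 1.0)``; zero-variance differences with
    a nonzero mean are an error (the statistic is undefined).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-d and equally long")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvaluationSummary:
    """Band x feature-set metric table with paired-test p-values."""

    per_subject: pd.DataFrame  # subject, band, feature_set, auc, acc, n_evals
    table: pd.DataFrame  # band x feature_set mean AUC/ACC
    ttests: pd.DataFrame  # band, metric, t, p
    notes: list[str] = field(default_factory=list)

    def mean_metric(self, band: str, feature_set: str, metric: str) -> float:
        sel = self.table[(self.table["band"] == band)
                         & (self.table["feature_set"] == feature_set)]
        if sel.empty:
            raise KeyError(f"no entry for {band}/{feature_set}")
        return float(sel[metric].iloc[0])


def summarize(per_subject_results: pd.DataFrame,
              expected_evals: int | None = None) -> EvaluationSummary:
    """Aggregate per-(subject, band, feature set) CV results.

    ``per_subject_results`` must hold one row per subject x band x
    feature_set with columns ``auc``, ``acc`` and ``n_evals`` (already
    averaged over the fold x test-couple grid).  Missing cells raise with
    their names; a single subject skips the t-tests with a warning.
    """
    req = {"subject", "band", "feature_set", "auc", "acc"}
    missing_cols = req - set(per_subject_results.columns)
    if missing_cols:
        raise ValueError(f"results missing columns: {sorted(missing_cols)}")
    df = per_subject_results
    subjects = sorted(df["subject"].unique(), key=str)
    bands = list(dict.fromkeys(df["band"]))
    sets = list(dict.fromkeys(df["feature_set"]))
    missing = [
        f"{s}/{b}/{fs}" for s in subjects for b in bands for fs in sets
        if df[(df.subject == s) & (df.band == b)
              & (df.feature_set == fs)].empty
    ]
    if missing:
        raise ValueError(f"missing result cells: {missing}")
    if expected_evals is not None and "n_evals" in df:
        bad = df[df["n_evals"] != expected_evals]
        if not bad.empty:
            raise ValueError(
                f"unexpected evaluation counts: {bad.to_dict('records')}")

    table = (df.groupby(["band", "feature_set"], sort=False)[["auc", "acc"]]
             .mean().reset_index())

    notes = []
    trows = []
    if len(subjects) < 2:
        warnings.warn("single subject: paired t-tests skipped")
        notes.append("t-tests skipped (single subject)")
    elif len(sets) == 2:
        for b in bands:
            for metric in ("auc", "acc"):
                va = [float(df[(df.subject == s) & (df.band == b)
                               & (df.feature_set == sets[0])][metric].iloc[0])
                      for s in subjects]
                vb = [float(df[(df.subject == s) & (df.band == b)
                               & (df.feature_set == sets[1])][metric].iloc[0])
                      for s in subjects]
                try:
                    t, p = paired_ttest(va, vb)
                except ValueError as exc:
                    notes.append(f"{b}/{metric}: {exc}")
                    t, p = np.nan, np.nan
                trows.append({"band": b, "metric": metric, "t": t, "p": p})
    ttests = pd.DataFrame(trows, columns=["band", "metric", "t", "p"])
    return EvaluationSummary(per_subject=df.reset_index(drop=True),
                             table=table, ttests=ttests, notes=notes)
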