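"""Stepwise linear discriminant analysis (SWLDA) via ordinary least squares.

The classifier regresses 0/1 class labels (eyes-closed OC = 1, eyes-open
OA = 0) on spectral features and builds the model stepwise:

* **forward**: among the excluded features, refit with each candidate added
  to the current model and take the one with the smallest two-sided
  coefficient p-value; enter it if p < ``alpha_enter`` (0.05);
* **backward**: while any included feature has p > ``alpha_remove`` (0.1),
  remove the least significant one; then try forward again.

The candidate scan is computed by projecting candidates onto the orthogonal
complement of the current design, which yields exactly the same t-statistic
as a full OLS refit per candidate (partial-F equivalence for a single
term) at a fraction of the cost.  Columns are standardized internally for
conditioning; reported weights are mapped back to the original scale.
Ties resolve to the lowest column index, so fits are deterministic.

The discriminant score of an epoch is ``intercept + w . x`` with features
matched to the model *by name*, so column order at scoring time is free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SWLDAConfig",
    "FeatureMatrix",
    "SWLDAModel",
    "fit_swlda",
    "discriminant_scores",
]

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class SWLDAConfig:
    """Entry/removal significance levels and safety caps.

    ``max_features=None`` lets the rules terminate selection on their own
    (bounded by the row count); pipelines working on dense spectral grids
    typically cap it.
    """

    alpha_enter: float = 0.05
    alpha_remove: float = 0.1
    max_features: int | None = None
    max_iterations: int = 500

    def __post_init__(self):
        if not (0 < self.alpha_enter < 1 and 0 < self.alpha_remove < 1):
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.alpha_enter > self.alpha_remove:
            warnings.warn("alpha_enter > alpha_remove invites entry/removal "
                          "cycling; the standard setting is 0.05 / 0.1")


@dataclass
class FeatureMatrix:
    """Epochs x features design with binary labels and feature names."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-d (epochs x features)")
        if self.X.shape[0] != self.y.size:
            raise ValueError("row count of X must match label count")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match X columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("labels must be coded 0/1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]


@dataclass
class SWLDAModel:
    feature_names: list[str]  # in entry order
    weights: np.ndarray  # original feature scale
    intercept: float
    trace: list[dict] = field(default_factory=list)
    stop_reason: str = "converged"
    config: SWLDAConfig = field(default_factory=SWLDAConfig)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def _ols_pvalues(Z: np.ndarray, y: np.ndarray):
    """OLS of y on [1, Z]; returns (coefs, p-values of the Z columns)."""
    n = Z.shape[0]
    D = np.column_stack([np.ones(n), Z])
    k = D.shape[1]
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    df = n - k
    if df <= 0:
        raise np.linalg.LinAlgError("no residual degrees of freedom")
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.pinv(D.T @ D)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 1e-300))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return beta, pvals[1:]


def fit_swlda(features: FeatureMatrix, config: SWLDAConfig = SWLDAConfig()
              ) -> SWLDAModel:
    """Run forward-entry / backward-removal stepwise selection.

    Each outer iteration adds at most one feature, then runs backward
    elimination to exhaustion; the fit stops when neither rule fires (the
    model may be empty).  Rank-deficient candidates are skipped with a
    trace entry.  On normal convergence the model satisfies the stepwise
    invariant: every included feature has p < ``alpha_remove`` and no
    excluded feature would enter with p < ``alpha_enter``.
    """
    n, m = features.n, features.m
    y = features.y
    n1 = int(y.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both classes must be present in the labels")
    if n1 < 2 or n - n1 < 2:
        raise ValueError("need at least 2 epochs per class")

    mu = features.X.mean(axis=0)
    sd = features.X.std(axis=0, ddof=0)
    constant = sd < _RANK_TOL * (np.abs(mu) + 1.0)
    sd_safe = np.where(constant, 1.0, sd)
    Z = (features.X - mu) / sd_safe

    max_size = n - 3  # keep >=1 residual df when testing an entrant
    if config.max_features is not None:
        max_size = min(max_size, config.max_features)

    selected: list[int] = []
    trace: list[dict] = []
    seen_states: set[frozenset] = set()
    stop_reason = "converged"
    it = 0

    while True:
        it += 1
        if it > config.max_iterations:
            stop_reason = "max_iterations"
            break
        changed = False

        # ---- forward: vectorized candidate scan --------------------------
        if len(selected) < max_size:
            cand = np.array([j for j in range(m)
                             if j not in selected and not constant[j]],
                            dtype=int)
            if cand.size:
                D = np.column_stack([np.ones(n)] + [Z[:, j] for j in selected])
                Q, _ = np.linalg.qr(D)
                r = y - Q @ (Q.T @ y)
                rss_cur = float(r @ r)
                Xc = Z[:, cand]
                Xperp = Xc - Q @ (Q.T @ Xc)
                d = np.einsum("ij,ij->j", Xperp, Xperp)
                ok = d > _RANK_TOL * n
                for j in cand[~ok]:
                    trace.append({"iteration": it, "action": "skip",
                                  "feature": features.feature_names[j],
                                  "reason": "rank-deficient"})
                df = n - (len(selected) + 2)
                if ok.any() and df >= 1:
                    xy = Xperp.T @ y
                    rss_new = rss_cur - np.where(ok, xy ** 2 / np.where(
                        ok, d, 1.0), 0.0)
                    rss_new = np.maximum(rss_new, 0.0)
                    sigma2 = rss_new / df
                    with np.errstate(divide="ignore", invalid="ignore"):
                        t2 = np.where(ok & (sigma2 > 0),
                                      (xy ** 2 / np.where(ok, d, 1.0))
                                      / np.where(sigma2 > 0, sigma2, 1.0),
                                      np.where(ok, np.inf, -np.inf))
                    pvals = 2.0 * stats.t.sf(np.sqrt(np.maximum(t2, 0.0)), df)
                    pvals[~ok] = np.inf
                    best = int(np.argmin(pvals))  # ties -> lowest index
                    if pvals[best] < config.alpha_enter:
                        j = int(cand[best])
                        selected.append(j)
                        trace.append({"iteration": it, "action": "add",
                                      "feature": features.feature_names[j],
                                      "p": float(pvals[best])})
                        changed = True

        # ---- backward: remove to exhaustion ------------------------------
        while selected:
            _, p_in = _ols_pvalues(Z[:, selected], y)
            worst = int(np.argmax(p_in))  # ties -> earliest entrant
            if p_in[worst] > config.alpha_remove:
                j = selected.pop(worst)
                trace.append({"iteration": it, "action": "remove",
                              "feature": features.feature_names[j],
                              "p": float(p_in[worst])})
                changed = True
            else:
                break

        if not changed:
            break
        state = frozenset(selected)
        if state in seen_states:
            stop_reason = "cycle"
            warnings.warn("stepwise selection entered a cycle; stopping")
            break
        seen_states.add(state)

    # ---- final OLS on the selected set, mapped to original scale ---------
    if selected:
        beta, _ = _ols_pvalues(Z[:, selected], y)
        w_std = beta[1:]
        w = w_std / sd_safe[selected]
        intercept = float(beta[0] - np.sum(w_std * mu[selected]
                                           / sd_safe[selected]))
        weights = np.asarray(w, dtype=float)
    else:
        intercept = float(y.mean())
        weights = np.empty(0)

    model = SWLDAModel(
        feature_names=[features.feature_names[j] for j in selected],
        weights=weights, intercept=intercept, trace=trace,
        stop_reason=stop_reason, config=config,
    )
    if stop_reason == "converged":
        _check_invariant(model, features, Z, selected, constant, config, n, m)
    return model


def _check_invariant(model, features, Z, selected, constant, config, n, m):
    if selected:
        _, p_in = _ols_pvalues(Z[:, selected], y=features.y)
        if np.any(p_in > config.alpha_remove + 1e-12):
            raise AssertionError("stepwise invariant violated: included "
                                 "feature above alpha_remove")
    if len(selected) >= n - 3 or (config.max_features is not None
                                  and len(selected) >= config.max_features):
        return  # entry was capped, excluded features may still be eligible
    cand = [j for j in range(m) if j not in selected and not constant[j]]
    if not cand:
        return
    y = features.y
    D = np.column_stack([np.ones(n)] + [Z[:, j] for j in selected])
    Q, _ = np.linalg.qr(D)
    r = y - Q @ (Q.T @ y)
    rss_cur = float(r @ r)
    Xc = Z[:, cand]
    Xperp = Xc - Q @ (Q.T @ Xc)
    d = np.einsum("ij,ij->j", Xperp, Xperp)
    ok = d > _RANK_TOL * n
    df = n - (len(selected) + 2)
    if df < 1 or not ok.any():
        return
    xy = Xperp.T @ y
    rss_new = np.maximum(rss_cur - np.where(ok, xy ** 2 / np.where(
        ok, d, 1.0), 0.0), 0.0)
    sigma2 = rss_new / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(ok & (sigma2 > 0),
                      (xy ** 2 / np.where(ok, d, 1.0))
                      / np.where(sigma2 > 0, sigma2, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.sqrt(np.maximum(t2, 0.0)), df)
    pvals[~ok] = np.inf
    if np.min(pvals) < config.alpha_enter - 1e-12:
        raise AssertionError("stepwise invariant violated: excluded feature "
                             "below alpha_enter")


def discriminant_scores(model: SWLDAModel,
                        features: FeatureMatrix) -> np.ndarray:
    """Linear discriminant function values; higher scores favour OC (= 1).

    Feature columns are matched to the model by *name*; a missing named
    feature raises.
    """
    idx = []
    for name in model.feature_names:
        try:
            idx.append(features.feature_names.index(name))
        except ValueError:
            raise KeyError(f"feature {name!r} missing from the scoring "
                           "matrix") from None
    if not idx:
        return np.full(features.n, model.intercept)
    return model.intercept + features.X[:, idx] @ model.weights
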