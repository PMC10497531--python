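"""General-factor (D) scores and explained common variance (ECV).

Scores use the regression (Thurstone) method, F-hat = Psi Lambda' Sigma^-1
(x - x_bar), which is determinate and closed-form given the fitted loadings
and the model-implied covariance. The ECV of a trait scale is the proportion
of its common variance carried by the general factor — its D saturation —
computed from completely standardized loadings so it is invariant to the
units of individual items.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bifactor import BifactorFit, ModelSpec, implied_sigma

__all__ = ["ScoreVector", "score_general_factor", "ecv", "correlate_scores", "standardized_loadings"]


@dataclass(frozen=True)
class ScoreVector:
    """Per-respondent general-factor scores from one fitted model."""

    values: np.ndarray
    sign_flipped: bool
    model_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size


def standardized_loadings(fit: BifactorFit, spec: ModelSpec | None = None):
    """Completely standardized loadings: lambda * sqrt(psi) / item SD, with
    item SDs taken from the model-implied covariance."""
    spec = spec or fit.spec
    sigma = implied_sigma(fit.params, spec)
    sd = np.sqrt(np.diag(sigma))
    lg = fit.params.lam_g * np.sqrt(fit.params.psi[0]) / sd
    ls = fit.params.lam_s * np.sqrt(fit.params.psi[1:][spec.item_scale_index]) / sd
    return lg, ls


def score_general_factor(X, fit: BifactorFit, spec: ModelSpec | None = None) -> ScoreVector:
    """Regression-method D scores, sign-aligned so the sum of standardized
    general loadings is positive.

    Raises if the fitted general factor carries no information (all general
    loadings effectively zero) or the implied covariance is singular.
    """
    spec = spec or fit.spec
    if isinstance(X, pd.DataFrame):
        if list(X.columns) != list(spec.scale_map.item_ids):
            X = X.loc[:, list(spec.scale_map.item_ids)]
        A = X.to_numpy(dtype=float)
    else:
        A = np.asarray(X, dtype=float)
    if A.shape[1] != spec.p:
        raise ValueError(f"X has {A.shape[1]} columns, spec expects {spec.p}")
    if not fit.converged:
        warnings.warn("scoring a non-converged fit", stacklevel=2)

    lg_std, _ = standardized_loadings(fit, spec)
    if np.max(np.abs(lg_std)) < 1e-8:
        raise ValueError("general factor is degenerate: all general loadings ~ 0")

    sigma = implied_sigma(fit.params, spec)
    lam = fit.params.loading_matrix(spec)
    try:
        weights = np.linalg.solve(sigma, lam * fit.params.psi)  # p x (T+1)
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied covariance is singular; cannot compute scores") from exc
    scores = (A - A.mean(axis=0)) @ weights[:, 0]

    flip = lg_std.sum() < 0
    if flip:
        scores = -scores
    return ScoreVector(values=scores, sign_flipped=bool(flip))


def ecv(fit: BifactorFit, spec: ModelSpec | None = None) -> pd.Series:
    """Per-scale explained common variance from standardized loadings:

        ECV_t = sum_i lg_i^2 / (sum_i lg_i^2 + sum_i ls_i^2), items i in t.

    A scale with zero common variance gets NaN with a warning.
    """
    spec = spec or fit.spec
    lg, ls = standardized_loadings(fit, spec)
    out = {}
    for t, name in enumerate(spec.scale_map.scale_names):
        idx = spec.scale_map.scale_indices(name)
        g2 = float(np.sum(lg[idx] ** 2))
        s2 = float(np.sum(ls[idx] ** 2))
        if g2 + s2 <= 0:
            warnings.warn(f"scale {name!r} has zero common variance; ECV undefined", stacklevel=2)
            out[name] = np.nan
        else:
            out[name] = g2 / (g2 + s2)
    return pd.Series(out, name="ecv")


def correlate_scores(a, b) -> float:
    """Pearson correlation of two score vectors (already sign-aligned, so the
    signed r is reported — no absolute value)."""
    av = a.values if isinstance(a, ScoreVector) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, ScoreVector) else np.asarray(b, dtype=float)
    if av.size != bv.size:
        raise ValueError("score vectors differ in length")
    if av.size < 3:
        raise ValueError("need at least 3 observations")
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("zero-variance score vector")
    return float(np.corrcoef(av, bv)[0, 1])
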