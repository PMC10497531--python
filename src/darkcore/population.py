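"""Synthetic Likert item responses from a known bifactor population model.

Items are generated from a latent-normal model: each item i of trait scale t
has a latent value

    y*_i = lambda_g[i] * F_D + lambda_s[i] * F_t + eps_i,

where F_D (the general "dark" factor), the T scale-specific factors F_t and
the residuals eps_i are mutually independent standard normals, except that
eps_i has variance 1 - lambda_g[i]^2 - lambda_s[i]^2 so that y* has unit
variance. Likert responses 1-5 are obtained by cutting y* at four strictly
increasing thresholds per item; shifting all thresholds upward pushes the
observed distribution toward the floor (category 1), which is how the
floor-effect (Sadism-like) scale is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ScaleSpec",
    "PopulationModel",
    "make_default_population",
    "make_gradient_population",
    "generate",
    "implied_covariance",
    "population_ecv",
    "expected_item_means",
    "write_responses",
    "write_scale_map_csv",
]

#: default symmetric thresholds on the latent standard-normal metric
BASE_THRESHOLDS = np.array([-1.8, -0.6, 0.6, 1.8])


@dataclass(frozen=True)
class ScaleSpec:
    """One trait scale: its items' loadings and Likert thresholds.

    Parameters
    ----------
    name
        Short scale label (used to build item IDs ``name.1``, ``name.2``, ...).
    general_loadings
        Standardized loadings of each item on the general factor, each in
        (-1, 1).
    specific_loadings
        Standardized loadings on the scale's own specific factor, each in
        (-1, 1).
    thresholds
        Array of shape ``(n_items, 4)``; strictly increasing cut-points per
        item mapping the latent continuum to categories 1-5.
    """

    name: str
    general_loadings: np.ndarray
    specific_loadings: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.general_loadings, dtype=float)
        s = np.asarray(self.specific_loadings, dtype=float)
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.ndim == 1:
            thr = np.tile(thr, (g.size, 1))
        object.__setattr__(self, "general_loadings", g)
        object.__setattr__(self, "specific_loadings", s)
        object.__setattr__(self, "thresholds", thr)
        if g.shape != s.shape or g.ndim != 1:
            raise ValueError(f"scale {self.name!r}: loading vectors must be 1-D and equal length")
        if thr.shape != (g.size, 4):
            raise ValueError(f"scale {self.name!r}: thresholds must have shape (n_items, 4)")
        if np.any(np.abs(g) >= 1) or np.any(np.abs(s) >= 1):
            raise ValueError(f"scale {self.name!r}: loadings must lie in (-1, 1)")
        if np.any(g**2 + s**2 >= 1):
            raise ValueError(f"scale {self.name!r}: item communality >= 1 (non-positive residual variance)")
        if np.any(np.diff(thr, axis=1) <= 0):
            raise ValueError(f"scale {self.name!r}: thresholds must be strictly increasing per item")

    @property
    def n_items(self) -> int:
        return self.general_loadings.size

    @property
    def residual_variances(self) -> np.ndarray:
        return 1.0 - self.general_loadings**2 - self.specific_loadings**2


@dataclass(frozen=True)
class PopulationModel:
    """Orthogonal bifactor population: one general factor + one specific factor
    per scale, all with unit variance."""

    scales: tuple[ScaleSpec, ...]

    def __post_init__(self):
        object.__setattr__(self, "scales", tuple(self.scales))
        names = [s.name for s in self.scales]
        if len(set(names)) != len(names):
            raise ValueError("duplicate scale names in population model")

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    @property
    def n_items(self) -> int:
        return sum(s.n_items for s in self.scales)

    @property
    def scale_names(self) -> list[str]:
        return [s.name for s in self.scales]

    @property
    def item_ids(self) -> list[str]:
        return [f"{s.name}.{j + 1}" for s in self.scales for j in range(s.n_items)]

    @property
    def item_scale(self) -> list[str]:
        return [s.name for s in self.scales for _ in range(s.n_items)]

    @property
    def general_loadings(self) -> np.ndarray:
        return np.concatenate([s.general_loadings for s in self.scales])

    @property
    def specific_loadings(self) -> np.ndarray:
        return np.concatenate([s.specific_loadings for s in self.scales])

    @property
    def thresholds(self) -> np.ndarray:
        return np.vstack([s.thresholds for s in self.scales])

    def loading_matrix(self) -> np.ndarray:
        """p x (1 + T) loading matrix; column 0 is the general factor."""
        p, T = self.n_items, self.n_scales
        lam = np.zeros((p, T + 1))
        lam[:, 0] = self.general_loadings
        start = 0
        for t, s in enumerate(self.scales):
            lam[start : start + s.n_items, t + 1] = s.specific_loadings
            start += s.n_items
        return lam


# ---------------------------------------------------------------------------
# default population: 16 aversive trait scales, p = 151 items
# ---------------------------------------------------------------------------

# (name, n_items, general-loading range, specific-loading range, threshold shift)
# D-saturation spans a gradient: Frustralia-, Machiavellianism- and
# Crudelia-like scales are nearly absorbed by the general factor, while
# SD3-Narcissism-, Entitlement- and Greed-like scales are dominated by
# specific variance. Threshold shifts place the expected observed item means
# between ~1.9 and ~2.9, except the Sadism-like scale whose strong right
# shift produces a floor effect (expected mean ~1.45).
_DEFAULT_SCALES = [
    ("crudelia", 13, (0.60, 0.70), (0.25, 0.35), 0.55),
    ("egoism", 12, (0.50, 0.60), (0.35, 0.45), 0.15),
    ("entitlement", 9, (0.28, 0.38), (0.55, 0.65), 0.35),
    ("exploitativeness", 6, (0.48, 0.58), (0.38, 0.48), 1.00),
    ("frustralia", 14, (0.65, 0.75), (0.20, 0.30), 0.45),
    ("greed", 7, (0.30, 0.40), (0.55, 0.65), 0.25),
    ("machiavellianism", 9, (0.62, 0.72), (0.22, 0.32), 0.65),
    ("moral_disengagement", 8, (0.45, 0.55), (0.40, 0.50), 0.90),
    ("narcissism_sd3", 9, (0.25, 0.35), (0.58, 0.68), 0.50),
    ("narcissism_narq", 6, (0.42, 0.52), (0.45, 0.55), 0.75),
    ("selfishness", 8, (0.55, 0.65), (0.30, 0.40), 1.10),
    ("psychopathy", 9, (0.58, 0.68), (0.28, 0.38), 1.20),
    ("sadism", 10, (0.55, 0.65), (0.30, 0.40), 2.10),
    ("self_centeredness", 4, (0.55, 0.65), (0.30, 0.40), 1.30),
    ("spitefulness", 17, (0.50, 0.60), (0.35, 0.45), 0.85),
    ("vengefulness", 10, (0.48, 0.58), (0.38, 0.48), 0.70),
]


def make_default_population() -> PopulationModel:
    """Default 16-scale population (151 items, 17 orthogonal factors).

    Loadings vary linearly across the items of each scale within the ranges
    above; thresholds are the symmetric defaults shifted rightward by a
    per-scale offset, with the Sadism-like scale shifted far enough to
    produce the floor effect seen in its observed mean.
    """
    scales = []
    for name, n, (g_lo, g_hi), (s_lo, s_hi), delta in _DEFAULT_SCALES:
        scales.append(
            ScaleSpec(
                name=name,
                general_loadings=np.linspace(g_lo, g_hi, n),
                specific_loadings=np.linspace(s_lo, s_hi, n),
                thresholds=np.tile(BASE_THRESHOLDS + delta, (n, 1)),
            )
        )
    return PopulationModel(scales=tuple(scales))


def make_gradient_population(
    n_scales: int = 8,
    items_per_scale: int = 4,
    general_range: tuple[float, float] = (0.20, 0.75),
    specific_range: tuple[float, float] = (0.70, 0.20),
) -> PopulationModel:
    """Small stylized population with a planted D-saturation gradient.

    Scale ``s1`` has the lowest general loadings (and highest specific
    loadings); the last scale has the highest. Useful for scaled-down
    end-to-end runs where the identity of the best and worst trait is known
    by construction. Thresholds are the symmetric defaults for all scales.
    """
    if n_scales < 2 or items_per_scale < 2:
        raise ValueError("need at least 2 scales with 2 items each")
    g_levels = np.linspace(*general_range, n_scales)
    s_levels = np.linspace(*specific_range, n_scales)
    scales = []
    for t in range(n_scales):
        scales.append(
            ScaleSpec(
                name=f"s{t + 1}",
                general_loadings=np.full(items_per_scale, g_levels[t]),
                specific_loadings=np.full(items_per_scale, s_levels[t]),
                thresholds=np.tile(BASE_THRESHOLDS, (items_per_scale, 1)),
            )
        )
    return PopulationModel(scales=tuple(scales))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate(
    model: PopulationModel,
    n: int,
    seed: int,
    likert: bool = True,
    return_factors: bool = False,
):
    """Draw an n x p item-response matrix from the population model.

    Factor scores and residuals are independent standard normals; with
    ``likert=True`` the latent values are cut at each item's thresholds into
    categories 1-5. The same ``(model, n, seed, likert)`` always yields a
    bitwise-identical matrix. If discretization produces a constant column
    (possible at small n with extreme thresholds), the draw is retried with a
    deterministically derived sub-seed.

    Returns a DataFrame indexed 0..n-1 with item-ID columns; with
    ``return_factors=True`` also the n x (1+T) DataFrame of true factor
    scores (column ``general`` first).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    resid_var = np.concatenate([s.residual_variances for s in model.scales])
    if np.any(resid_var <= 0):
        raise ValueError("degenerate model: non-positive residual variance")
    lam = model.loading_matrix()
    thr = model.thresholds
    p, T = model.n_items, model.n_scales

    for attempt in range(20):
        rng = np.random.default_rng((seed + attempt * 1_000_003) % 2**63)
        F = rng.standard_normal((n, T + 1))
        eps = rng.standard_normal((n, p)) * np.sqrt(resid_var)
        Y = F @ lam.T + eps
        if likert:
            X = 1 + (Y[:, :, None] > thr[None, :, :]).sum(axis=2)
            X = X.astype(np.int64)
        else:
            X = Y
        if X.std(axis=0).min() > 0:
            break
    else:
        raise ValueError("could not generate data without constant columns; increase n")

    df = pd.DataFrame(X, columns=model.item_ids)
    if return_factors:
        fdf = pd.DataFrame(F, columns=["general"] + model.scale_names)
        return df, fdf
    return df


def implied_covariance(model: PopulationModel) -> np.ndarray:
    """Population covariance Lambda Lambda' + Theta on the latent metric.

    Orthogonal unit-variance factors give a unit diagonal; items of different
    scales covary only through the general factor (lambda_g,i * lambda_g,j).
    """
    lam = model.loading_matrix()
    resid = np.concatenate([s.residual_variances for s in model.scales])
    sigma = lam @ lam.T + np.diag(resid)
    return (sigma + sigma.T) / 2.0


def population_ecv(model: PopulationModel) -> pd.Series:
    """True per-scale explained common variance from the population loadings."""
    out = {}
    for s in model.scales:
        g2 = np.sum(s.general_loadings**2)
        s2 = np.sum(s.specific_loadings**2)
        out[s.name] = g2 / (g2 + s2)
    return pd.Series(out, name="ecv")


def expected_item_means(model: PopulationModel) -> pd.Series:
    """Closed-form expected observed Likert mean per item.

    Each latent item value is marginally standard normal, so the expected
    category is 1 + sum_c P(y* > t_c) = 1 + sum_c (1 - Phi(t_c)).
    """
    means = 1.0 + norm.sf(model.thresholds).sum(axis=1)
    return pd.Series(means, index=model.item_ids, name="expected_mean")


def write_responses(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def write_scale_map_csv(model: PopulationModel, path) -> None:
    """Companion scale map: item_id, scale_name, reverse_coded (all False —
    simulated items are generated already consistently keyed)."""
    pd.DataFrame(
        {
            "item_id": model.item_ids,
            "scale_name": model.item_scale,
            "reverse_coded": False,
        }
    ).to_csv(path, index=False)
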