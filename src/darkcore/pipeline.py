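"""Exhaustive trait-subset enumeration and reduced-model refits.

For every subset of k trait scales (k_min <= k <= k_max) the bifactor model
is refit on the subset's item columns, the reduced general factor ("reduced
D") is scored, and its Pearson correlation with the full-model D scores is
recorded. Summaries reproduce the study design: per-k medians and tail
percentiles, per-trait conditional distributions, composition of the extreme
1% of subsets, and comparisons of conventional named sets (Dark Triad /
Tetrad and their NARQ variants) against size-matched baselines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .bifactor import FitOptions, ModelSpec, ScaleMap, fit, sample_covariance, subset_seed
from .scores import ScoreVector, correlate_scores, score_general_factor

__all__ = [
    "CombinationResult",
    "SummaryTable",
    "enumerate_subsets",
    "run_reduced",
    "run_all",
    "summarize",
    "tail_composition",
    "named_sets",
    "stopping_diagnostic",
    "DEFAULT_NAMED_SETS",
]

#: conventional trait sets, in terms of the default population's scale names
DEFAULT_NAMED_SETS = {
    "dark_triad": ["machiavellianism", "narcissism_sd3", "psychopathy"],
    "dark_tetrad": ["machiavellianism", "narcissism_sd3", "psychopathy", "sadism"],
    "dark_triad_narq": ["machiavellianism", "narcissism_narq", "psychopathy"],
    "dark_tetrad_narq": ["machiavellianism", "narcissism_narq", "psychopathy", "sadism"],
}


@dataclass(frozen=True)
class CombinationResult:
    """One trait subset with its reduced-D vs full-D correlation."""

    subset: tuple[str, ...]
    k: int
    r: float  # NaN iff the reduced fit failed
    converged: bool
    df: int

    def __post_init__(self):
        object.__setattr__(self, "subset", tuple(self.subset))
        if len(set(self.subset)) != len(self.subset):
            raise ValueError("subset contains duplicate traits")
        if self.k != len(self.subset):
            raise ValueError("k must equal the subset size")
        if np.isfinite(self.r) and not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")


@dataclass
class SummaryTable:
    """Aggregates over combination results (Table-1 / Fig-2 analogues)."""

    by_k: pd.DataFrame  # k, n_combinations, n_failed, median, p1, p5, p10
    by_trait: pd.DataFrame  # trait, k, n, median, p25, p75
    grand_median: float
    n_failed: int
    metadata: dict = field(default_factory=dict)


def enumerate_subsets(traits, k_min: int = 2, k_max: int = 11) -> list[tuple[str, ...]]:
    """All size-k subsets of the trait names for k in [k_min, k_max], each
    sorted, in deterministic lexicographic order within k."""
    traits = list(traits)
    if len(set(traits)) != len(traits):
        raise ValueError("duplicate trait names")
    if not (1 <= k_min <= k_max <= len(traits)):
        raise ValueError(f"invalid k range [{k_min}, {k_max}] for {len(traits)} traits")
    ordered = sorted(traits)
    out = []
    for k in range(k_min, k_max + 1):
        out.extend(combinations(ordered, k))
    return out


def run_reduced(
    subset,
    X,
    full_scores: ScoreVector,
    scale_map: ScaleMap,
    options: FitOptions | None = None,
    global_seed: int = 0,
) -> CombinationResult:
    """Refit the bifactor model on one subset of trait scales and correlate
    the reduced D scores with the full-model scores.

    The engine seed is derived from (global_seed, subset), so results do not
    depend on execution order or worker count. A failed reduced fit yields a
    missing r with ``converged=False``.
    """
    subset = tuple(sorted(subset))
    options = options or FitOptions()
    options = replace(options, seed=subset_seed(global_seed, subset))
    sub_map = scale_map.subset(subset)
    spec = ModelSpec(sub_map)
    Xs = X.loc[:, list(sub_map.item_ids)]
    S = sample_covariance(Xs)
    res = fit(S, Xs.shape[0], spec, options)
    if not res.converged:
        return CombinationResult(subset=subset, k=len(subset), r=float("nan"), converged=False, df=res.df)
    reduced_scores = score_general_factor(Xs, res, spec)
    r = correlate_scores(reduced_scores, full_scores)
    return CombinationResult(subset=subset, k=len(subset), r=r, converged=True, df=res.df)


def run_all(
    X,
    scale_map: ScaleMap,
    k_min: int = 2,
    k_max: int = 11,
    options: FitOptions | None = None,
    workers: int = 1,
    seed: int = 0,
):
    """Fit the full model once, score it, then refit every trait subset.

    Returns ``(results, manifest)``: results in enumeration order regardless
    of worker count, and a manifest recording the seed, options and the
    failed-fit count (a warning status is set when more than 5% of reduced
    fits fail).
    """
    options = options or FitOptions()
    spec = ModelSpec(scale_map)
    S = sample_covariance(X)
    full_fit = fit(S, X.shape[0], spec, replace(options, seed=seed))
    full_scores = score_general_factor(X, full_fit, spec)

    subsets = enumerate_subsets(scale_map.scale_names, k_min, k_max)
    if workers == 1:
        results = [run_reduced(s, X, full_scores, scale_map, options, seed) for s in subsets]
    else:
        results = Parallel(n_jobs=workers)(
            delayed(run_reduced)(s, X, full_scores, scale_map, options, seed) for s in subsets
        )
    n_failed = sum(1 for r in results if not r.converged)
    frac = n_failed / len(results) if results else 0.0
    manifest = {
        "seed": seed,
        "k_min": k_min,
        "k_max": k_max,
        "workers": workers,
        "n_subsets": len(results),
        "n_failed": n_failed,
        "warning": frac > 0.05,
        "full_fit": {
            "converged": full_fit.converged,
            "f_ml": full_fit.f_ml,
            "chi_square": full_fit.chi_square,
            "df": full_fit.df,
            "rmsea": full_fit.rmsea,
            "srmr": full_fit.srmr,
        },
        "options": {
            "max_restarts": options.max_restarts,
            "jitter_sd": options.jitter_sd,
            "chi2_n": options.chi2_n,
            "variance_floor": options.variance_floor,
        },
    }
    if manifest["warning"]:
        warnings.warn(f"{n_failed}/{len(results)} reduced fits failed (> 5%)", stacklevel=2)
    return results, manifest


def _results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subset": [",".join(r.subset) for r in results],
            "k": [r.k for r in results],
            "r": [r.r for r in results],
            "converged": [r.converged for r in results],
            "df": [r.df for r in results],
        }
    )


def summarize(results) -> SummaryTable:
    """Per-k medians and 1st/5th/10th percentiles plus per-trait conditional
    summaries; failed fits are excluded with a reported count. Percentiles use
    linear interpolation between order statistics (recorded in metadata)."""
    if not results:
        raise ValueError("no results to summarize")
    df = _results_frame(results)
    ok = df[np.isfinite(df["r"])]
    n_failed = int(len(df) - len(ok))

    rows = []
    for k, grp in df.groupby("k", sort=True):
        vals = grp.loc[np.isfinite(grp["r"]), "r"].to_numpy()
        row = {"k": int(k), "n_combinations": int(len(grp)), "n_failed": int(len(grp) - vals.size)}
        if vals.size:
            row.update(
                median=float(np.median(vals)),
                p1=float(np.percentile(vals, 1, method="linear")),
                p5=float(np.percentile(vals, 5, method="linear")),
                p10=float(np.percentile(vals, 10, method="linear")),
            )
        else:
            row.update(median=np.nan, p1=np.nan, p5=np.nan, p10=np.nan, all_failed=True)
        rows.append(row)
    by_k = pd.DataFrame(rows)

    traits = sorted({t for r in results for t in r.subset})
    trows = []
    for trait in traits:
        mask = ok["subset"].str.split(",").apply(lambda s, t=trait: t in s)
        sub = ok[mask]
        for k, grp in sub.groupby("k", sort=True):
            vals = grp["r"].to_numpy()
            trows.append(
                {
                    "trait": trait,
                    "k": int(k),
                    "n": int(vals.size),
                    "median": float(np.median(vals)),
                    "p25": float(np.percentile(vals, 25, method="linear")),
                    "p75": float(np.percentile(vals, 75, method="linear")),
                }
            )
    by_trait = pd.DataFrame(trows)

    grand = float(np.median(ok["r"])) if len(ok) else float("nan")
    return SummaryTable(
        by_k=by_k,
        by_trait=by_trait,
        grand_median=grand,
        n_failed=n_failed,
        metadata={"percentile_method": "linear interpolation between order statistics"},
    )


def tail_composition(results, k: int, tail: float = 0.01, side: str = "bottom") -> pd.Series:
    """Fraction of the extreme-``tail`` subsets of size k containing each trait.

    ``side='bottom'`` takes the lowest correlations, ``'top'`` the highest;
    ties at the cutoff are all included.
    """
    if side not in ("bottom", "top"):
        raise ValueError("side must be 'bottom' or 'top'")
    if not 0 < tail <= 1:
        raise ValueError("tail must be in (0, 1]")
    at_k = [r for r in results if r.k == k and np.isfinite(r.r)]
    if not at_k:
        raise ValueError(f"no converged results at k={k}")
    m = max(1, math.ceil(tail * len(at_k)))
    rs = np.array([r.r for r in at_k])
    order = np.argsort(rs, kind="stable")
    if side == "top":
        order = order[::-1]
    cutoff = rs[order[m - 1]]
    if side == "bottom":
        selected = [at_k[i] for i in range(len(at_k)) if rs[i] <= cutoff]
    else:
        selected = [at_k[i] for i in range(len(at_k)) if rs[i] >= cutoff]
    traits = sorted({t for r in at_k for t in r.subset})
    freq = {t: sum(1 for r in selected if t in r.subset) / len(selected) for t in traits}
    return pd.Series(freq, name=f"{side}_{tail:g}_k{k}")


def named_sets(results, definitions) -> pd.DataFrame:
    """Correlations of named trait sets against size-matched baselines.

    For each named set: its own r, the median r of all same-size subsets, and
    the median r of same-size subsets containing each member trait (long
    format, one row per (set, comparison))."""
    df = _results_frame(results)
    ok = df[np.isfinite(df["r"])]
    lookup = {tuple(sorted(s.split(","))): r for s, r in zip(ok["subset"], ok["r"])}
    all_traits = {t for r in results for t in r.subset}
    rows = []
    for name, members in definitions.items():
        members = tuple(sorted(members))
        unknown = set(members) - all_traits
        if unknown:
            raise ValueError(f"named set {name!r} references unknown traits: {sorted(unknown)}")
        k = len(members)
        same_k = ok[ok["k"] == k]
        if same_k.empty:
            raise ValueError(f"no results of size {k} for named set {name!r}")
        r_set = lookup.get(members, float("nan"))
        rows.append({"set": name, "k": k, "comparison": "set_itself", "r": r_set})
        rows.append({"set": name, "k": k, "comparison": "median_all", "r": float(np.median(same_k["r"]))})
        for trait in members:
            mask = same_k["subset"].str.split(",").apply(lambda s, t=trait: t in s)
            med = float(np.median(same_k.loc[mask, "r"])) if mask.any() else float("nan")
            rows.append({"set": name, "k": k, "comparison": f"median_containing_{trait}", "r": med})
    return pd.DataFrame(rows)


def stopping_diagnostic(
    X,
    scale_map: ScaleMap,
    k: int,
    options: FitOptions | None = None,
    workers: int = 1,
    seed: int = 0,
) -> float:
    """Improvement in the per-k median correlation from size k to k+1.

    Used to justify a k_max: enumeration can stop once this increment drops
    below a negligible threshold (.005 in the original design).
    """
    if k + 1 > scale_map.n_scales:
        raise ValueError("k+1 exceeds the number of scales")
    results, _ = run_all(X, scale_map, k_min=k, k_max=k + 1, options=options, workers=workers, seed=seed)
    s = summarize(results)
    med = s.by_k.set_index("k")["median"]
    return float(med.loc[k + 1] - med.loc[k])
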