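"""Configuration, CSV/JSON I/O, manifests and report assembly.

File conventions: comma-separated CSV, header row, UTF-8, '.' decimal.
Reverse-coded items (flagged in the scale map) are re-scored as 6 - x when
responses are loaded, so all downstream analysis sees consistently keyed
items.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bifactor import FitOptions, ScaleMap
from .pipeline import DEFAULT_NAMED_SETS, CombinationResult, SummaryTable

__all__ = [
    "RunConfig",
    "load_config",
    "read_scale_map",
    "load_responses",
    "write_combinations",
    "read_combinations",
    "write_summary",
    "write_manifest",
    "assemble_report",
]

_KNOWN_KEYS = {
    "data",
    "scale_map",
    "out_dir",
    "k_min",
    "k_max",
    "seed",
    "workers",
    "named_sets",
    "engine",
}
_KNOWN_ENGINE_KEYS = {"max_restarts", "jitter_sd", "maxiter", "gtol", "ftol", "variance_floor", "chi2_n"}


@dataclass
class RunConfig:
    """Validated configuration of one full pipeline run."""

    data: str
    scale_map: str
    out_dir: str = "out"
    k_min: int = 2
    k_max: int = 11
    seed: int = 0
    workers: int = 1
    named_sets: dict = field(default_factory=lambda: dict(DEFAULT_NAMED_SETS))
    engine: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self):
        if not self.data:
            raise ValueError("config field 'data': a responses CSV path is required")
        if not self.scale_map:
            raise ValueError("config field 'scale_map': a scale-map CSV path is required")
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError(f"config fields k_min/k_max: invalid range [{self.k_min}, {self.k_max}]")
        if self.workers < 1:
            raise ValueError("config field 'workers': must be >= 1")
        for name, members in self.named_sets.items():
            if not isinstance(members, (list, tuple)) or len(members) < 2:
                raise ValueError(f"named set {name!r}: must list at least 2 traits")


def load_config(path) -> RunConfig:
    """Read a YAML run configuration, filling defaults and rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    engine_raw = raw.pop("engine", {}) or {}
    unknown_e = set(engine_raw) - _KNOWN_ENGINE_KEYS
    if unknown_e:
        raise ValueError(f"unknown engine option keys: {sorted(unknown_e)}")
    engine = FitOptions(**engine_raw)
    return RunConfig(engine=engine, **raw)


def read_scale_map(path) -> ScaleMap:
    """Read a scale map CSV with columns item_id, scale_name[, reverse_coded]."""
    df = pd.read_csv(path)
    required = {"item_id", "scale_name"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scale map missing columns: {sorted(missing)}")
    rev = df["reverse_coded"].astype(bool).tolist() if "reverse_coded" in df.columns else None
    return ScaleMap(
        item_ids=tuple(df["item_id"].astype(str)),
        item_scale=tuple(df["scale_name"].astype(str)),
        reverse_coded=tuple(rev) if rev is not None else None,
    )


def load_responses(path, scale_map: ScaleMap) -> pd.DataFrame:
    """Read a responses CSV in scale-map column order, re-scoring
    reverse-coded items as 6 - x."""
    df = pd.read_csv(path)
    missing = [i for i in scale_map.item_ids if i not in df.columns]
    if missing:
        raise ValueError(f"responses CSV missing items: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    df = df.loc[:, list(scale_map.item_ids)]
    for item, rev in zip(scale_map.item_ids, scale_map.reverse_coded):
        if rev:
            df[item] = 6 - df[item]
    return df


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------


def write_combinations(results, path) -> None:
    pd.DataFrame(
        {
            "subset": [",".join(r.subset) for r in results],
            "k": [r.k for r in results],
            "r": [r.r for r in results],
            "converged": [r.converged for r in results],
            "df": [r.df for r in results],
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_combinations(path) -> list[CombinationResult]:
    df = pd.read_csv(path)
    return [
        CombinationResult(
            subset=tuple(row.subset.split(",")),
            k=int(row.k),
            r=float(row.r) if np.isfinite(row.r) else float("nan"),
            converged=bool(row.converged),
            df=int(row.df),
        )
        for row in df.itertuples()
    ]


def write_summary(summary: SummaryTable, out_dir) -> None:
    out = Path(out_dir)
    summary.by_k.to_csv(out / "summary_by_k.csv", index=False, float_format="%.10g")
    summary.by_trait.to_csv(out / "by_trait.csv", index=False, float_format="%.10g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir, config_echo: dict, run_manifest: dict, input_paths=(), timings=None) -> None:
    out = Path(out_dir)
    checksums = {}
    for p in list(input_paths) + sorted(out.glob("*.csv")):
        p = Path(p)
        if p.exists():
            checksums[p.name] = _sha256(p)
    manifest = {
        "config": config_echo,
        "run": run_manifest,
        "timings_seconds": timings or {},
        "checksums": checksums,
        "version": _version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _version() -> str:
    from . import __version__

    return __version__


def assemble_report(out_dir) -> str:
    """Assemble a single human-readable markdown report from a completed run
    directory (summary tables, per-trait panels, named-set comparisons,
    convergence summary, manifest echo). Writes and returns report.md."""
    out = Path(out_dir)
    needed = ["summary_by_k.csv", "by_trait.csv", "named_sets.csv", "manifest.json"]
    missing = [f for f in needed if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"run incomplete; missing outputs: {missing}")
    by_k = pd.read_csv(out / "summary_by_k.csv")
    by_trait = pd.read_csv(out / "by_trait.csv")
    nsets = pd.read_csv(out / "named_sets.csv")
    manifest = json.loads((out / "manifest.json").read_text())

    lines = ["# Reduced-D approximation report", ""]
    run = manifest.get("run", {})
    lines += [
        f"Subsets evaluated: {run.get('n_subsets', '?')} "
        f"(k in [{run.get('k_min', '?')}, {run.get('k_max', '?')}]); "
        f"failed fits: {run.get('n_failed', '?')}.",
        "",
        "## Correlation of reduced D with full D, by number of traits",
        "",
        by_k.to_markdown(index=False),
        "",
        "## Conditional on included trait",
        "",
        by_trait.to_markdown(index=False),
        "",
        "## Named trait sets vs size-matched baselines",
        "",
        nsets.to_markdown(index=False),
        "",
        "## Full-model fit",
        "",
        "```json",
        json.dumps(run.get("full_fit", {}), indent=2),
        "```",
        "",
        "## Manifest",
        "",
        "```json",
        json.dumps(manifest, indent=2, sort_keys=True),
        "```",
        "",
    ]
    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    return text
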