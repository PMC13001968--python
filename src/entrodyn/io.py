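"""Readers, writers, run configuration and the end-to-end pipeline.

File formats are deliberately plain: comma-separated UTF-8 CSV with a
mandatory header and '.' decimals for tables and trajectories, YAML or
JSON for parameter specs, JSON (full float precision, sorted keys) for
reports.  Every report names the entropy scale used ("norm" or "bits")
and the seed, so reruns with an identical configuration are
byte-identical.

Likert long format: columns ``item_id, wave_label, wave_time,
cat_1..cat_k``.  Items may use fewer categories than the widest item by
leaving trailing category cells empty.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import Trajectory
from .entropy import (
    EntropySeries,
    LikertWaveTable,
    PooledEntropyIndex,
    entropy_series,
    pooled_entropy_index,
)
from .errors import InvalidInputError, SchemaError
from .estimation import (
    DEFAULT_BOUNDS,
    ObservedTrajectories,
    ParamEntry,
    PARAM_NAMES,
    ParameterSpec,
    fit_multistart,
)
from .validation import loo_validate, sensitivity_scan, trait_metrics

__all__ = [
    "read_likert_csv",
    "write_likert_csv",
    "series_by_item",
    "write_entropy_csv",
    "read_entropy_csv",
    "write_pooled_csv",
    "observed_from_series",
    "write_trajectory_csv",
    "read_param_spec",
    "write_param_spec",
    "write_json_report",
    "RunConfig",
    "run_pipeline",
]

_CAT_RE = re.compile(r"^cat_(\d+)$")


def read_likert_csv(path) -> List[LikertWaveTable]:
    """Read the long-format Likert count table.

    Validates the schema and reports offending rows by their 1-based
    data row number (header excluded).
    """
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    required = ["item_id", "wave_label", "wave_time"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    cat_cols = sorted(
        (c for c in df.columns if _CAT_RE.match(c)),
        key=lambda c: int(_CAT_RE.match(c).group(1)),
    )
    if len(cat_cols) < 2:
        raise SchemaError(f"{path}: need at least two cat_<k> columns")
    dupes = df.duplicated(subset=["item_id", "wave_label"], keep=False)
    if dupes.any():
        rows = [int(i) + 1 for i in df.index[dupes]]
        raise SchemaError(f"{path}: duplicate (item, wave) rows at data rows {rows}")
    tables: List[LikertWaveTable] = []
    for idx, row in df.iterrows():
        raw = row[cat_cols].to_numpy(dtype=float)
        # trailing NaNs mark items with fewer categories; interior gaps are errors
        valid = ~np.isnan(raw)
        if valid.any() and not valid[: int(np.flatnonzero(valid)[-1]) + 1].all():
            raise SchemaError(
                f"{path}: interior empty category cell at data row {int(idx) + 1}"
            )
        counts = raw[valid]
        if counts.size < 2:
            raise SchemaError(
                f"{path}: fewer than 2 category counts at data row {int(idx) + 1}"
            )
        if np.any(counts < 0):
            raise SchemaError(f"{path}: negative count at data row {int(idx) + 1}")
        if np.any(counts != np.rint(counts)):
            raise SchemaError(
                f"{path}: non-integer count at data row {int(idx) + 1}"
            )
        try:
            tables.append(
                LikertWaveTable(
                    item_id=str(row["item_id"]),
                    wave_label=str(row["wave_label"]),
                    wave_time=float(row["wave_time"]),
                    counts=counts.astype(np.int64),
                )
            )
        except InvalidInputError as exc:
            raise SchemaError(f"{path}: data row {int(idx) + 1}: {exc}") from exc
    return tables


def write_likert_csv(tables: Sequence[LikertWaveTable], path) -> None:
    k = max(t.n_categories for t in tables)
    rows = []
    for t in tables:
        row = {"item_id": t.item_id, "wave_label": t.wave_label,
               "wave_time": t.wave_time}
        for i in range(k):
            row[f"cat_{i + 1}"] = t.counts[i] if i < t.n_categories else None
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def series_by_item(tables: Sequence[LikertWaveTable]) -> Dict[str, EntropySeries]:
    """Group wave tables by item and compute each item's entropy series."""
    groups: Dict[str, list] = {}
    for t in tables:
        groups.setdefault(t.item_id, []).append(t)
    return {item: entropy_series(rows) for item, rows in sorted(groups.items())}


def write_entropy_csv(series: Sequence[EntropySeries], path) -> None:
    rows = []
    for s in series:
        for t, hb, hn in zip(s.wave_times, s.entropy_bits, s.entropy_norm):
            rows.append({"item_id": s.item_id, "wave_time": t,
                         "entropy_bits": hb, "entropy_norm": hn,
                         "n_categories": s.n_categories})
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def read_entropy_csv(path) -> List[EntropySeries]:
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    required = ["item_id", "wave_time", "entropy_bits", "entropy_norm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    out = []
    for item, g in df.groupby("item_id", sort=True):
        g = g.sort_values("wave_time")
        if "n_categories" in df.columns:
            n_cat = int(g["n_categories"].iloc[0])
        else:
            # infer from bits/norm ratio: log2(n) = bits / norm
            ratio = (g["entropy_bits"] / g["entropy_norm"]).median()
            n_cat = int(round(2.0 ** ratio))
        out.append(
            EntropySeries(
                item_id=str(item),
                wave_times=g["wave_time"].to_numpy(float),
                entropy_bits=g["entropy_bits"].to_numpy(float),
                entropy_norm=g["entropy_norm"].to_numpy(float),
                n_categories=n_cat,
            )
        )
    return out


def write_pooled_csv(index: PooledEntropyIndex, path) -> None:
    pd.DataFrame(
        {"wave_time": index.wave_times, "h_star": index.h_star,
         "n_items": index.n_items}
    ).to_csv(path, index=False, encoding="utf-8")


def observed_from_series(
    series_n: EntropySeries, series_p: EntropySeries, scale: str = "norm"
) -> ObservedTrajectories:
    """Map two item entropy series onto the model's N and P traits."""
    if not np.array_equal(series_n.wave_times, series_p.wave_times):
        raise InvalidInputError(
            f"items {series_n.item_id!r} and {series_p.item_id!r} "
            "are on different wave grids"
        )
    if scale == "norm":
        return ObservedTrajectories(series_n.wave_times, series_n.entropy_norm,
                                    series_p.entropy_norm)
    if scale == "bits":
        return ObservedTrajectories(series_n.wave_times, series_n.entropy_bits,
                                    series_p.entropy_bits)
    raise InvalidInputError(f"scale must be 'norm' or 'bits', got {scale!r}")


def write_trajectory_csv(traj: Trajectory, path) -> None:
    traj.as_dataframe().to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Parameter-spec files
# ---------------------------------------------------------------------------

def read_param_spec(path, obs: Optional[ObservedTrajectories] = None) -> ParameterSpec:
    """Load a parameter spec from YAML or JSON.

    Layout::

        forcing_enabled: false
        coupled: true
        parameters:
          mu:  {free: true, start: 0.05, lower: 0.0, upper: 1.0}
          K:   {free: false, value: 0.5}
          N0:  {free: false, value: data}   # pin to first observed wave

    Missing parameters fall back to package defaults.  ``value: data``
    (valid for N0/P0) requires ``obs``.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: spec must be a mapping")
    params = raw.get("parameters", {})
    entries = {}
    for name, cfg in params.items():
        if name not in PARAM_NAMES:
            raise SchemaError(f"{path}: unknown parameter {name!r}")
        cfg = dict(cfg or {})
        lo, hi = DEFAULT_BOUNDS[name]
        lo = float(cfg.pop("lower", lo))
        hi = float(cfg.pop("upper", hi))
        free = bool(cfg.pop("free", False))
        value = cfg.pop("value", None)
        start = cfg.pop("start", None)
        if cfg:
            raise SchemaError(f"{path}: {name}: unknown keys {sorted(cfg)}")
        if value == "data":
            if name not in ("N0", "P0"):
                raise SchemaError(f"{path}: value 'data' only valid for N0/P0")
            if obs is None:
                raise SchemaError(
                    f"{path}: {name}: value 'data' requires observed data"
                )
            value = (obs.n_observed if name == "N0" else obs.p_observed)[0]
        if value is None:
            value = start if start is not None else (lo + hi) / 2.0
        entries[name] = ParamEntry(
            free, float(value), lo, hi,
            None if start is None else float(start),
        )
    return ParameterSpec(
        entries,
        forcing_enabled=bool(raw.get("forcing_enabled", False)),
        coupled=bool(raw.get("coupled", True)),
    )


def write_param_spec(spec: ParameterSpec, path) -> None:
    path = Path(path)
    data = spec.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def write_json_report(data: dict, path) -> None:
    """Deterministic JSON: sorted keys, full float precision, no clock."""
    Path(path).write_text(
        json.dumps(data, indent=2, sort_keys=True, allow_nan=True) + "\n",
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of the end-to-end pipeline run."""

    likert_csv: str
    out_dir: str
    item_n: Optional[str] = None
    item_p: Optional[str] = None
    spec_path: Optional[str] = None
    spec_kind: str = "full"  # "full" | "reduced" (ignored when spec_path set)
    scale: str = "norm"
    seed: int = 20260319
    n_starts: int = 32
    do_loo: bool = False
    do_sensitivity: bool = False
    sensitivity_mode: str = "perturb_only"
    loo_n_starts: int = 8
    verbose: bool = False

    def __post_init__(self):
        if not Path(self.likert_csv).exists():
            raise InvalidInputError(f"input file not found: {self.likert_csv}")
        if self.spec_path is not None and not Path(self.spec_path).exists():
            raise InvalidInputError(f"spec file not found: {self.spec_path}")
        if self.scale not in ("norm", "bits"):
            raise InvalidInputError(f"scale must be 'norm' or 'bits': {self.scale!r}")
        if self.spec_kind not in ("full", "reduced"):
            raise InvalidInputError(
                f"spec_kind must be 'full' or 'reduced': {self.spec_kind!r}"
            )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def run_pipeline(config: RunConfig) -> dict:
    """entropy -> fit -> metrics (-> loo -> sensitivity), all on disk.

    Writes ``entropy.csv``, ``pooled.csv``, ``fit.json``,
    ``metrics.json`` (plus ``loo.json`` / ``sensitivity.csv`` when
    requested) and a ``provenance.json`` record into ``out_dir``.
    Reruns with an identical config and seed are byte-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = print if config.verbose else (lambda *a, **k: None)

    tables = read_likert_csv(config.likert_csv)
    series = series_by_item(tables)
    log(f"computed entropy for {len(series)} items")
    write_entropy_csv(list(series.values()), out_dir / "entropy.csv")
    pooled = pooled_entropy_index(list(series.values()))
    write_pooled_csv(pooled, out_dir / "pooled.csv")

    items = sorted(series)
    item_n = config.item_n if config.item_n is not None else items[0]
    item_p = config.item_p if config.item_p is not None else items[min(1, len(items) - 1)]
    for item in (item_n, item_p):
        if item not in series:
            raise InvalidInputError(f"item {item!r} not present in the data")
    obs = observed_from_series(series[item_n], series[item_p], config.scale)

    if config.spec_path is not None:
        spec = read_param_spec(config.spec_path, obs)
    elif config.spec_kind == "reduced":
        spec = ParameterSpec.reduced(obs)
    else:
        spec = ParameterSpec.full(obs)

    fit = fit_multistart(spec, obs, n_starts=config.n_starts, seed=config.seed)
    log(f"fit SSE={fit.sse:.6g} (best of {config.n_starts} starts)")
    fit_record = fit.to_dict()
    fit_record["scale"] = config.scale
    fit_record["items"] = {"N": item_n, "P": item_p}
    write_json_report(fit_record, out_dir / "fit.json")

    metrics = {trait: rep.to_dict()
               for trait, rep in trait_metrics(obs, fit).items()}
    metrics["scale"] = config.scale
    write_json_report(metrics, out_dir / "metrics.json")

    results = {"fit": fit, "metrics": metrics, "items": (item_n, item_p)}

    if config.do_loo:
        loo = loo_validate(obs, spec, n_starts=config.loo_n_starts,
                           seed=config.seed)
        rec = loo.to_dict()
        rec["scale"] = config.scale
        write_json_report(rec, out_dir / "loo.json")
        results["loo"] = loo
        log(f"LOO RMSE N={loo.loo_rmse_n:.4g} P={loo.loo_rmse_p}")

    if config.do_sensitivity:
        sens = sensitivity_scan(fit, obs, spec, mode=config.sensitivity_mode)
        sens.as_dataframe().to_csv(out_dir / "sensitivity.csv", index=False,
                                   encoding="utf-8")
        results["sensitivity"] = sens

    provenance = {
        "package": "entrodyn",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "scale": config.scale,
        "parameter_spec": spec.to_dict(),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    write_json_report(provenance, out_dir / "provenance.json")
    return results
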