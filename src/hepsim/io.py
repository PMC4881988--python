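"""Result writers: per-trial CSV, aggregate CSV, and a run manifest."""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd

from .config import ConfigDocument, config_hash
from .experiments import AggregateResult

__all__ = ["write_results", "write_manifest"]


def write_results(agg: AggregateResult, out_dir: str | Path, prefix: str) -> list[Path]:
    """Write per-trial and aggregate CSVs; returns the written paths.

    Per-trial rows: (trial, seed, selector, cycle, count); aggregate rows:
    (selector, cycle, mean, sd, n).  Raises on empty results.
    """
    if not agg.trials or not agg.trials[0].series:
        raise ValueError("no measurements to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, tr in enumerate(agg.trials):
        for sel, series in tr.series.items():
            for cyc, val in series:
                rows.append((i, tr.seed, sel, cyc, val))
        for key, val in tr.scalars.items():
            rows.append((i, tr.seed, key, -1, val))
    trial_path = out / f"{prefix}_trials.csv"
    pd.DataFrame(
        rows, columns=["trial", "seed", "selector", "cycle", "count"]
    ).to_csv(trial_path, index=False)

    arows = []
    for sel in agg.mean:
        for cyc, m, s in zip(agg.cycles[sel], agg.mean[sel], agg.sd[sel]):
            arows.append((sel, cyc, m, s, agg.n_trials))
    agg_path = out / f"{prefix}_aggregate.csv"
    pd.DataFrame(
        arows, columns=["selector", "cycle", "mean", "sd", "n"]
    ).to_csv(agg_path, index=False)
    return [trial_path, agg_path]


def write_manifest(
    doc: ConfigDocument,
    out_dir: str | Path,
    protocol: str,
    base_seed: int,
    trials: int,
    scale: float,
    wall_seconds: float,
) -> Path:
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "protocol": protocol,
        "config_hash": config_hash(doc),
        "base_seed": base_seed,
        "trial_seeds": [base_seed + i for i in range(trials)],
        "scale": scale,
        "version": __version__,
        "wall_seconds": round(wall_seconds, 3),
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out / f"{protocol}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
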