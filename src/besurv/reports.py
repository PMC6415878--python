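"""Table emitters and run manifests.

Formatted CSVs follow the published table layouts: money in £ mln to one
decimal, counts as integers, percentages to one decimal. A parallel "raw"
CSV keeps full precision. Every command writes a manifest (JSON) listing the
emitted files, written last.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .analyses import CostConsequenceResult
from .cohort import round_half_up

__all__ = [
    "mln",
    "pct",
    "RunManifest",
    "write_table",
    "cost_consequence_tables",
    "budget_impact_table",
]


def mln(x: float) -> float:
    """GBP to £ mln, one decimal."""
    return round(x / 1e6, 1)


def pct(x: float) -> float | None:
    """Fraction to percent, one decimal; NaN passes through as None."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    return round(100.0 * x, 1)


def _package_version() -> str:
    try:
        return version("besurv")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


@dataclass
class RunManifest:
    """Record of one CLI run: inputs, settings and every emitted file."""

    command: str
    config: str | None = None
    scenario: int | None = None
    seed: int | None = None
    outputs: list[str] = field(default_factory=list)

    def add(self, path: Path) -> Path:
        self.outputs.append(str(path))
        return path

    def write(self, out_dir: Path) -> Path:
        payload = {
            "command": self.command,
            "config": self.config,
            "scenario": self.scenario,
            "seed": self.seed,
            "package_version": _package_version(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "outputs": sorted(self.outputs),
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def write_table(frame: pd.DataFrame, out_dir: Path, name: str, manifest: RunManifest) -> Path:
    path = out_dir / f"{name}.csv"
    frame.to_csv(path)
    return manifest.add(path)


def cost_consequence_tables(cc: CostConsequenceResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(formatted, raw) cost-consequence tables.

    Rows are the cost categories (£ mln) followed by the outcome counts
    (integers); columns are NBI, HD-WLE, absolute and relative difference.
    """
    raw = cc.table()
    formatted = raw.copy()
    cost_rows = cc.cost_table().index
    for col in ("nbi", "hdwle", "abs_diff"):
        formatted.loc[cost_rows, col] = [mln(v) for v in raw.loc[cost_rows, col]]
        count_rows = [r for r in raw.index if r not in cost_rows]
        formatted.loc[count_rows, col] = [
            int(round_half_up(v)) for v in raw.loc[count_rows, col]
        ]
    formatted["rel_diff"] = [pct(v) for v in raw["rel_diff"]]
    formatted = formatted.rename(
        columns={
            "nbi": "NBI",
            "hdwle": "HD-WLE",
            "abs_diff": "absolute_difference",
            "rel_diff": "relative_difference_pct",
        }
    )
    return formatted, raw


def budget_impact_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Format a budget-impact table: money in £ mln, population as integers."""
    formatted = raw.copy()
    for col in ("nbi_cost", "hdwle_cost", "difference"):
        formatted[col] = [mln(v) for v in raw[col]]
    formatted["population"] = raw["population"].astype(int)
    return formatted.rename(
        columns={
            "population": "population",
            "nbi_cost": "NBI_mln",
            "hdwle_cost": "HD-WLE_mln",
            "difference": "difference_mln",
        }
    )
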