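"""End-to-end pipeline: simulate or load a cohort, classify over the
lookback grid, compute the misclassification metrics, and write artifacts.

Outputs of :func:`run`:

* ``classifications.csv`` — patient x condition x L group assignments;
* ``metrics.csv`` — the condition x L metrics grid;
* ``summary.txt`` — per-condition incidence at the gold-standard and
  shortest lookbacks, their change, and the headline false-positive
  statistics (a textual analogue of the incidence-vs-lookback figures);
* ``manifest.json`` — config digest, seed, versions and row counts,
  sufficient to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .classify import DEFAULT_L_GRID, run_grid
from .codebook import ConditionCodebook
from .cohort import CohortDataset, read_cohort, write_cohort
from .simulate import SimulationConfig, simulate

__all__ = ["RunConfig", "run", "summarize"]

logger = logging.getLogger("claims_lookback")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulate mode or files mode)."""

    out_dir: str | Path
    sim: Optional[SimulationConfig] = None
    patients_path: Optional[str | Path] = None
    claims_path: Optional[str | Path] = None
    codebook_path: Optional[str | Path] = None  # None -> builtin
    L_grid: Sequence[int] = DEFAULT_L_GRID
    incidence_months: int = 3
    gold_L: Optional[int] = None
    pair_pooling: str = "pooled"
    mixed_rule: bool = False
    write_dataset: bool = False  # mirror simulated cohort to out_dir

    def __post_init__(self) -> None:
        simulate_mode = self.sim is not None
        files_mode = self.patients_path is not None or self.claims_path is not None
        if simulate_mode == files_mode:
            raise ValueError(
                "exactly one input mode required: sim=... or patients_path/claims_path"
            )
        if files_mode and (self.patients_path is None or self.claims_path is None):
            raise ValueError("files mode needs both patients_path and claims_path")
        if self.pair_pooling not in ("pooled", "per_setting"):
            raise ValueError(f"invalid pair_pooling: {self.pair_pooling!r}")
        grid = sorted(set(int(L) for L in self.L_grid))
        if self.gold_L is None:
            self.gold_L = max(grid)
        if self.gold_L not in grid:
            raise ValueError(f"gold_L={self.gold_L} not in L grid {grid}")
        self.L_grid = grid


def _config_digest(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    payload["sim"] = config.sim.to_dict() if config.sim is not None else None
    for key in ("out_dir", "patients_path", "claims_path", "codebook_path"):
        payload[key] = str(payload[key]) if payload[key] is not None else None
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _load_inputs(config: RunConfig) -> tuple[CohortDataset, ConditionCodebook]:
    if config.codebook_path is not None:
        path = Path(config.codebook_path)
        if not path.exists():
            raise FileNotFoundError(f"codebook_path does not exist: {path}")
        codebook = ConditionCodebook.from_csv(path)
    else:
        codebook = ConditionCodebook.builtin()
    if config.sim is not None:
        logger.info(
            "simulating cohort: n=%d style=%s seed=%d",
            config.sim.n_patients,
            config.sim.cohort_style,
            config.sim.seed,
        )
        dataset, _truth = simulate(config.sim, codebook)
    else:
        logger.info("reading cohort from %s / %s", config.patients_path, config.claims_path)
        dataset = read_cohort(config.patients_path, config.claims_path)
    return dataset, codebook


def summarize(metrics_grid: pd.DataFrame) -> pd.DataFrame:
    """Per-condition summary of the lookback contrast.

    Reports incidence per 1,000 at the longest (gold) and shortest
    lookbacks, the absolute and relative change, the false positive
    fraction at the shortest lookback, and the percent of incident cases
    that are false positives at L=12 when present in the grid.
    """
    Ls = sorted(metrics_grid["lookback_months"].unique())
    if len(Ls) < 2:
        raise ValueError("summary needs at least two lookback lengths to contrast")
    lo, hi = Ls[0], Ls[-1]
    pivot = metrics_grid.set_index(["condition", "lookback_months"])
    rows = []
    for condition in metrics_grid["condition"].unique():
        inc_hi = pivot.at[(condition, hi), "incidence_per_1000"]
        inc_lo = pivot.at[(condition, lo), "incidence_per_1000"]
        row = {
            "condition": condition,
            f"incidence_at_{hi}m": inc_hi,
            f"incidence_at_{lo}m": inc_lo,
            "abs_change": inc_lo - inc_hi,
            "rel_change": (inc_lo - inc_hi) / inc_hi if inc_hi else float("nan"),
            f"fpf_at_{lo}m": pivot.at[(condition, lo), "false_positive_fraction"],
        }
        if 12 in Ls:
            row["pct_fp_at_12m"] = pivot.at[
                (condition, 12), "pct_incident_false_positive"
            ]
        rows.append(row)
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the pipeline; returns the paths of the written artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, codebook = _load_inputs(config)

    logger.info(
        "classifying %d patients, %d claims over L grid %s (gold %d)",
        dataset.n_patients,
        len(dataset.claims),
        config.L_grid,
        config.gold_L,
    )
    grid, records = run_grid(
        dataset,
        codebook,
        L_values=config.L_grid,
        incidence_months=config.incidence_months,
        gold_L=config.gold_L,
        pair_pooling=config.pair_pooling,
        mixed_rule=config.mixed_rule,
        return_records=True,
    )
    summary = summarize(grid)

    paths: dict[str, Path] = {}
    paths["classifications"] = out / "classifications.csv"
    records.to_csv(paths["classifications"], index=False)
    paths["metrics"] = out / "metrics.csv"
    grid.to_csv(paths["metrics"], index=False)
    paths["summary"] = out / "summary.txt"
    with open(paths["summary"], "w") as handle:
        handle.write(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        handle.write("\n")
    if config.write_dataset and config.sim is not None:
        paths.update(write_cohort(dataset, out))

    manifest = {
        "config_digest": _config_digest(config),
        "seed": config.sim.seed if config.sim is not None else None,
        "versions": {
            "claims_lookback": __version__,
            "pandas": pd.__version__,
        },
        "n_patients": dataset.n_patients,
        "n_claims": int(len(dataset.claims)),
        "n_classification_records": int(len(records)),
        "L_grid": list(config.L_grid),
        "gold_L": config.gold_L,
        "dataset_meta": dataset.meta,
    }
    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as handle:
        json.dump(manifest, handle, indent=2, default=str)
        handle.write("\n")
    logger.info("wrote %d artifacts to %s", len(paths), out)
    return paths
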