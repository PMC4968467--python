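"""Tracking-error metric and per-participant cell aggregation.

The per-trial response is the mean Euclidean cursor-to-target distance in
pixels over the *final 4000 ms* of the 5000 ms tracking period, at the
10 ms recording interval: the half-open window (1000 ms, 5000 ms], i.e.
exactly the last 400 of the 500 recorded samples (half-open to avoid
double-counting the boundary sample).

For analysis, trial errors are averaged within each participant x
coloration x contrast x set-size cell and the cell means are transformed
with a natural logarithm (errors are right-skewed, approximately
lognormal).  Mean-then-log is the default order; log-then-mean
(trial-level logs) is available through ``log_stage``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = ["ErrorWindow", "tracking_error", "tracking_error_batch",
           "aggregate_cells", "trial_log_table"]

CELL_KEYS = ["participant", "coloration", "contrast", "set_size"]


@dataclass(frozen=True)
class ErrorWindow:
    """Scoring window: the final ``window_ms`` of the tracking period."""

    window_ms: float = 4000.0
    sample_interval_ms: float = 10.0
    track_ms: float = 5000.0

    def __post_init__(self) -> None:
        if self.window_ms > self.track_ms:
            raise ValueError("window cannot exceed the tracking period")

    @property
    def n_samples(self) -> int:
        return round(self.window_ms / self.sample_interval_ms)


def tracking_error(
    target_path: np.ndarray, cursor_path: np.ndarray, win: ErrorWindow = ErrorWindow()
) -> float:
    """Mean cursor-target distance (px) over the final window.

    Both paths must be (n, 2) arrays on the same 10 ms time base covering
    the full tracking period.
    """
    target_path = np.asarray(target_path, dtype=float)
    cursor_path = np.asarray(cursor_path, dtype=float)
    if target_path.shape != cursor_path.shape:
        raise ValueError(
            f"paths differ in shape: {target_path.shape} vs {cursor_path.shape}"
        )
    k = win.n_samples
    if target_path.shape[0] < k:
        raise ValueError(f"paths too short ({target_path.shape[0]} samples) "
                         f"for a {k}-sample window")
    d = np.linalg.norm(target_path[-k:] - cursor_path[-k:], axis=-1)
    return float(d.mean())


def tracking_error_batch(
    target: np.ndarray, cursor: np.ndarray, win: ErrorWindow = ErrorWindow()
) -> np.ndarray:
    """Vectorized :func:`tracking_error` over (n_samples, n_trials, 2) stacks."""
    if target.shape != cursor.shape:
        raise ValueError("paths differ in shape")
    k = win.n_samples
    d = np.linalg.norm(target[-k:] - cursor[-k:], axis=-1)
    return d.mean(axis=0)


def aggregate_cells(
    trials: pd.DataFrame, log_stage: Literal["cell", "trial"] = "cell"
) -> pd.DataFrame:
    """Collapse trials to the participant x condition cell means used for
    modelling.

    Expects canonical trial columns (participant, coloration, contrast,
    set_size, mean_error_px, optionally is_practice).  Practice trials must
    already be excluded -- passing any raises.  Returns one row per cell
    with ``mean_error_px`` (cell mean) and ``log_error``.

    ``log_stage='cell'`` (default): natural log of the cell mean.
    ``log_stage='trial'``: mean of per-trial logs (geometric-mean cell).
    The two differ by Jensen's inequality; the default follows the reading
    that the transform is applied to participant mean errors.
    """
    if "is_practice" in trials.columns and bool(trials["is_practice"].any()):
        raise ValueError("practice trials must be excluded before aggregation")
    if (trials["mean_error_px"] <= 0).any():
        raise ValueError("non-positive tracking errors cannot be log-transformed")

    grouped = trials.groupby(CELL_KEYS, observed=True)["mean_error_px"]
    counts = grouped.size()
    full = pd.MultiIndex.from_product(
        [sorted(trials[k].unique()) for k in CELL_KEYS], names=CELL_KEYS)
    missing = full.difference(counts.index)
    if len(missing):
        raise ValueError(f"empty design cells: {missing.tolist()[:10]}")

    if log_stage == "cell":
        cells = grouped.mean().reset_index()
        cells["log_error"] = np.log(cells["mean_error_px"])
    elif log_stage == "trial":
        cells = grouped.agg(lambda x: np.mean(np.log(x))).reset_index()
        cells = cells.rename(columns={"mean_error_px": "log_error"})
        cells["mean_error_px"] = np.exp(cells["log_error"])
        cells = cells[CELL_KEYS + ["mean_error_px", "log_error"]]
    else:
        raise ValueError(f"log_stage must be 'cell' or 'trial', got {log_stage!r}")
    return cells.sort_values(CELL_KEYS, ignore_index=True)


def trial_log_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Trial-level response table: per-trial log errors, practice excluded.

    The alternative modelling granularity to :func:`aggregate_cells`: the
    mixed models can be fitted to these rows directly (one row per trial)
    instead of to participant x condition cell means.
    """
    if "is_practice" in trials.columns:
        trials = trials[~trials["is_practice"]]
    if (trials["mean_error_px"] <= 0).any():
        raise ValueError("non-positive tracking errors cannot be log-transformed")
    out = trials.copy()
    out["log_error"] = np.log(out["mean_error_px"])
    return out.reset_index(drop=True)
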