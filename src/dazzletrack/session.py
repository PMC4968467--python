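"""Experimental session construction and single-trial execution.

A session is six blocks -- one per combination of coloration (parallel,
orthogonal, binary) and contrast (high, low) -- presented in random order,
each block containing every group size a fixed number of times in shuffled
order.  With the default 8 repetitions per cell this yields the canonical
6 x 7 x 8 = 336 analysed trials, preceded by four flagged practice trials.
The repetition count is inferred from the trial total (336 / 42 = 8) and
held in config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .kinematics import MotionParams, simulate_trial_motion, STANDARD_SET_SIZES
from .observer import ObserverParams, simulate_cursor

__all__ = ["SessionDesign", "TrialSpec", "TrialRecord", "build_session", "run_trial"]

COLORATIONS = ("parallel", "orthogonal", "binary")
CONTRASTS = ("high", "low")


@dataclass(frozen=True)
class SessionDesign:
    """Factorial session layout; defaults give the 336-trial design."""

    colorations: tuple[str, ...] = COLORATIONS
    contrasts: tuple[str, ...] = CONTRASTS
    set_sizes: tuple[int, ...] = STANDARD_SET_SIZES
    reps_per_cell: int = 8
    n_practice: int = 4
    practice_set_size: int = 20
    highlight_ms: float = 1000.0
    track_ms: float = 5000.0

    def __post_init__(self) -> None:
        if self.reps_per_cell < 1:
            raise ValueError("reps_per_cell must be at least 1")

    @property
    def n_blocks(self) -> int:
        return len(self.colorations) * len(self.contrasts)

    @property
    def n_trials(self) -> int:
        """Non-practice trials per participant."""
        return self.n_blocks * len(self.set_sizes) * self.reps_per_cell


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial (conditions only, no outcome)."""

    block_index: int
    trial_index: int
    coloration: str
    contrast: str
    set_size: int
    is_practice: bool = False


@dataclass(frozen=True)
class TrialRecord:
    """A completed trial: its conditions plus the mean tracking error."""

    participant: str
    block_index: int
    trial_index: int
    coloration: str
    contrast: str
    set_size: int
    mean_error_px: float
    is_practice: bool = False


def build_session(design: SessionDesign, rng: np.random.Generator) -> list[TrialSpec]:
    """Schedule one participant's session.

    Blocks (one per coloration x contrast pair) are uniformly shuffled;
    within each block the set_size x repetition list is shuffled
    independently.  Practice trials are prepended, flagged, and use the
    first block's condition at the practice set size.
    """
    pairs = list(product(design.colorations, design.contrasts))
    order = rng.permutation(len(pairs))
    trials: list[TrialSpec] = []
    idx = 0
    for b, k in enumerate(order):
        coloration, contrast = pairs[k]
        if b == 0:
            for _ in range(design.n_practice):
                trials.append(TrialSpec(
                    block_index=b, trial_index=idx, coloration=coloration,
                    contrast=contrast, set_size=design.practice_set_size,
                    is_practice=True))
                idx += 1
        sizes = np.repeat(design.set_sizes, design.reps_per_cell)
        for size in sizes[rng.permutation(len(sizes))]:
            trials.append(TrialSpec(
                block_index=b, trial_index=idx, coloration=coloration,
                contrast=contrast, set_size=int(size)))
            idx += 1
    return trials


def run_trial(
    spec: TrialSpec,
    motion: MotionParams,
    obs: ObserverParams,
    rng: np.random.Generator,
    participant: str = "P01",
) -> TrialRecord:
    """Simulate one trial end to end and score it.

    Runs the motion for the highlight + tracking period, simulates the
    synthetic observer's cursor, and computes the mean cursor-target
    distance over the final error window.
    """
    from .metrics import ErrorWindow, tracking_error

    traj = simulate_trial_motion(spec.set_size, motion, rng)
    path = simulate_cursor(traj, obs, rng, condition=spec.coloration)
    err = tracking_error(path.target_positions, path.positions, ErrorWindow())
    return TrialRecord(
        participant=participant,
        block_index=spec.block_index,
        trial_index=spec.trial_index,
        coloration=spec.coloration,
        contrast=spec.contrast,
        set_size=spec.set_size,
        mean_error_px=float(err),
        is_practice=spec.is_practice,
    )
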