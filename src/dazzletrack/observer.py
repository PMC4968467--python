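"""Synthetic observer: a stand-in for the human participants.

The experiment's response variable is the mean cursor-to-target distance
while a participant tracks one highlighted square among identical moving
distractors.  This module replaces the human with an explicitly *synthetic*
mechanism able to reproduce the qualitative phenomena the statistics layer
must detect:

* a confusion effect -- tracking error grows with group size -- produced by
  occasional swaps of the believed target to a nearby distractor, at a rate
  proportional to the local distractor density;
* a coloration ordering (parallel > orthogonal > binary) injected through a
  per-condition multiplier on the swap rate;
* lognormal-like, right-skewed error distributions, arising from the
  mixture of baseline tracking noise and swap-inflated errors;
* between-participant heterogeneity via lognormal scaling of the motor
  noise and swap rate.

None of the parameters below are estimates of human behaviour; they are
invented defaults for a generative model (see the methods note for the
rationale behind each value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .kinematics import MotionParams, TrajectorySet, init_states, step_batch

__all__ = ["ObserverParams", "CursorPath", "simulate_cursor", "generate_dataset"]

#: Milliseconds between recorded cursor/target samples.
SAMPLE_INTERVAL_MS = 10.0

DEFAULT_SIMILARITY = {"parallel": 1.6, "orthogonal": 1.25, "binary": 1.0}


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the synthetic tracking mechanism.

    motor_sd
        SD (px) of isotropic Gaussian positional noise added per sample.
    lag_ms
        Tracking delay: the cursor sits on the believed target's position
        ``lag_ms`` earlier (plus noise).
    swap_base
        Per-frame probability scale of swapping the believed target to a
        distractor; multiplied by the similarity factor of the coloration
        condition and by the count of distractors within ``swap_radius``.
    swap_radius
        Radius (px) defining "nearby" distractors for swap eligibility.
    similarity
        Coloration-condition multiplier on ``swap_base``.  Larger values
        make a condition more confusable; the defaults order the conditions
        parallel > orthogonal > binary.
    participant_sd
        SD of the participant-level lognormal factor applied to both
        ``motor_sd`` and ``swap_base`` (0 disables heterogeneity).
    """

    motor_sd: float = 6.0
    lag_ms: float = 100.0
    swap_base: float = 5e-4
    swap_radius: float = 48.0
    similarity: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIMILARITY)
    )
    participant_sd: float = 0.25

    def __post_init__(self) -> None:
        for name in ("motor_sd", "lag_ms", "swap_base", "swap_radius", "participant_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        missing = {"parallel", "orthogonal", "binary"} - set(self.similarity)
        if missing:
            raise ValueError(f"similarity missing conditions: {sorted(missing)}")

    @property
    def lag_frames(self) -> int:
        return round(self.lag_ms / SAMPLE_INTERVAL_MS)


@dataclass
class CursorPath:
    """Cursor positions at 10 ms intervals over the tracking period.

    Aligned sample-for-sample with ``target_positions`` (the true target's
    centre over the same frames).
    """

    positions: np.ndarray  # (n_samples, 2)
    target_positions: np.ndarray  # (n_samples, 2)
    believed_index: np.ndarray  # (n_samples,) which square was tracked
    sample_interval_ms: float = SAMPLE_INTERVAL_MS


def _swap_step(
    pos: np.ndarray,
    believed: np.ndarray,
    swap_rate: np.ndarray,
    swap_radius: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One frame of believed-target dynamics, vectorized over trials.

    ``pos`` is (T, n, 2); ``believed`` (T,) int; ``swap_rate`` (T,) the
    per-frame probability per nearby distractor.  Returns the updated
    believed indices: with probability ``swap_rate * n_close`` the believed
    target switches to the nearest other square.
    """
    T, n, _ = pos.shape
    if n == 1:
        return believed
    rows = np.arange(T)
    bpos = pos[rows, believed]  # (T, 2)
    d2 = np.sum((pos - bpos[:, None, :]) ** 2, axis=-1)  # (T, n)
    d2[rows, believed] = np.inf
    n_close = np.sum(d2 <= swap_radius**2, axis=-1)  # (T,)
    p = np.minimum(swap_rate * n_close, 1.0)
    do_swap = rng.random(T) < p
    nearest = np.argmin(d2, axis=-1)
    return np.where(do_swap, nearest, believed)


def _simulate_batch(
    n_squares: int,
    n_trials: int,
    motion: MotionParams,
    motor_sd: np.ndarray,
    swap_rate: np.ndarray,
    lag_frames: int,
    swap_radius: float,
    rng: np.random.Generator,
    return_paths: bool = False,
):
    """Run motion + observer for a batch of same-set-size trials.

    Returns ``(cursor, target)`` arrays of shape (n_track, T, 2) where
    n_track is the number of tracking-period samples.  Motion runs through
    the highlight period first; the believed target starts as the true
    target at the end of the highlight, and the cursor follows the believed
    target's position ``lag_frames`` samples earlier plus isotropic noise.
    """
    T = n_trials
    n_highlight = round(motion.highlight_ms / 1000.0 * motion.frame_rate)
    n_track = motion.n_frames - n_highlight

    pos, heading = init_states(T * n_squares, motion, rng)
    pos = pos.reshape(T, n_squares, 2)
    heading = heading.reshape(T, n_squares)
    target = rng.integers(n_squares, size=T)

    for _ in range(n_highlight):
        pos, heading = step_batch(pos, heading, motion, rng)

    believed = target.copy()
    rows = np.arange(T)
    believed_pos = np.empty((n_track, T, 2))
    target_pos = np.empty((n_track, T, 2))
    believed_hist = np.empty((n_track, T), dtype=np.int64) if return_paths else None
    swap_rate = np.broadcast_to(np.asarray(swap_rate, dtype=float), (T,))

    for f in range(n_track):
        pos, heading = step_batch(pos, heading, motion, rng)
        believed = _swap_step(pos, believed, swap_rate, swap_radius, rng)
        believed_pos[f] = pos[rows, believed]
        target_pos[f] = pos[rows, target]
        if return_paths:
            believed_hist[f] = believed

    # Delayed pursuit: cursor rides the believed-target history lag_frames
    # back (clamped to the start, where the cursor sits on the cue).
    src = np.maximum(np.arange(n_track) - lag_frames, 0)
    cursor = believed_pos[src]
    motor_sd = np.broadcast_to(np.asarray(motor_sd, dtype=float), (T,))
    cursor = cursor + rng.normal(size=cursor.shape) * motor_sd[None, :, None]
    if return_paths:
        return cursor, target_pos, believed_hist
    return cursor, target_pos


def simulate_cursor(
    traj: TrajectorySet,
    obs: ObserverParams,
    rng: np.random.Generator,
    condition: str = "binary",
) -> CursorPath:
    """Simulate the cursor for one pre-computed trial of motion.

    The believed target is initialized to the true target at the end of the
    highlight period; each tracking frame it may swap to the nearest
    distractor with probability ``swap_base * similarity[condition] *
    (count of distractors within swap_radius)``.
    """
    if traj.n_squares < 1:
        raise ValueError("trajectory set is empty")
    if condition not in obs.similarity:
        raise ValueError(f"unknown condition {condition!r}")
    motion = traj.params
    n_highlight = round(motion.highlight_ms / 1000.0 * motion.frame_rate)
    n_track = traj.n_frames - n_highlight
    swap_rate = obs.swap_base * obs.similarity[condition]

    believed = np.asarray([traj.target_index])
    believed_pos = np.empty((n_track, 2))
    believed_hist = np.empty(n_track, dtype=np.int64)
    for f in range(n_track):
        pos = traj.positions[n_highlight + f][None, :, :]  # (1, n, 2)
        believed = _swap_step(pos, believed, np.asarray([swap_rate]),
                              obs.swap_radius, rng)
        believed_pos[f] = pos[0, believed[0]]
        believed_hist[f] = believed[0]

    src = np.maximum(np.arange(n_track) - obs.lag_frames, 0)
    cursor = believed_pos[src] + rng.normal(scale=obs.motor_sd,
                                            size=(n_track, 2))
    return CursorPath(
        positions=cursor,
        target_positions=traj.positions[n_highlight:, traj.target_index, :],
        believed_index=believed_hist,
    )


def participant_factors(
    n_participants: int, obs: ObserverParams, rng: np.random.Generator
) -> np.ndarray:
    """Lognormal participant scaling factors (1.0 everywhere if sd = 0)."""
    if obs.participant_sd == 0:
        return np.ones(n_participants)
    return rng.lognormal(mean=0.0, sigma=obs.participant_sd, size=n_participants)


def generate_dataset(
    design=None,
    obs: ObserverParams | None = None,
    n_participants: int = 14,
    rng: np.random.Generator | None = None,
    motion: MotionParams | None = None,
) -> pd.DataFrame:
    """Generate a full synthetic experiment: one row per participant-trial.

    Emulates the per-trial records of the real dataset: participant,
    block, coloration, contrast, set size and mean tracking error (px) over
    the final 4000 ms, with practice trials included and flagged.  The
    default design is 14 participants x (4 practice + 336 trials).

    Implementation note: trials are simulated in batches grouped by set
    size (the per-frame work vectorizes over trials), which makes the full
    design tractable; results are deterministic given ``rng``.
    """
    from .session import SessionDesign, build_session
    from .metrics import ErrorWindow, tracking_error_batch

    if design is None:
        design = SessionDesign()
    obs = obs or ObserverParams()
    motion = motion or MotionParams(highlight_ms=design.highlight_ms,
                                    track_ms=design.track_ms)
    rng = rng or np.random.default_rng()

    factors = participant_factors(n_participants, obs, rng)
    specs = []
    for p in range(n_participants):
        for t in build_session(design, rng):
            specs.append((p, t))

    frame = pd.DataFrame({
        "participant": [f"P{p + 1:02d}" for p, t in specs],
        "block_index": [t.block_index for _, t in specs],
        "trial_index": [t.trial_index for _, t in specs],
        "coloration": [t.coloration for _, t in specs],
        "contrast": [t.contrast for _, t in specs],
        "set_size": [t.set_size for _, t in specs],
        "is_practice": [t.is_practice for _, t in specs],
    })
    pidx = np.asarray([p for p, _ in specs])
    sim = np.asarray([obs.similarity[t.coloration] for _, t in specs])
    motor_sd = obs.motor_sd * factors[pidx]
    swap_rate = obs.swap_base * sim * factors[pidx]

    win = ErrorWindow()
    errors = np.empty(len(frame))
    for size in sorted(frame["set_size"].unique()):
        mask = (frame["set_size"] == size).to_numpy()
        cursor, target = _simulate_batch(
            int(size), int(mask.sum()), motion,
            motor_sd[mask], swap_rate[mask],
            obs.lag_frames, obs.swap_radius, rng,
        )
        errors[mask] = tracking_error_batch(target, cursor, win)
    frame["mean_error_px"] = errors
    return frame
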