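"""Confined correlated random walk of the moving squares.

Each square moves at constant speed; every frame its heading changes by a
wrapped-normal ("circular Gaussian") increment with mean zero and a fixed
circular SD, so continuing straight is always the most probable direction.
Square orientation is locked to heading, which is why patterns are defined
in the object frame (see :mod:`dazzletrack.patterns`).

Coordinates: origin at the arena centre, +x rightward, +y upward, angles in
radians counter-clockwise from +x.  Positions are continuous (sub-pixel).

Confinement: squares are constrained to a central square arena.  The rule
applied here (the choice is a modelling decision, see the package methods
note) confines the square's *centre*: a step that would exit triggers up to
``max_redraws`` fresh heading increments, after which the heading is
reflected about the violated wall, which always produces an inward step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import pi, tau
from typing import Literal
import warnings

import numpy as np

__all__ = [
    "MotionParams",
    "SquareState",
    "TrajectorySet",
    "STANDARD_SET_SIZES",
    "step_heading",
    "advance",
    "step_batch",
    "simulate_trial_motion",
    "trajectories_to_frame",
]

#: Group sizes used in the factorial design.
STANDARD_SET_SIZES = (1, 10, 20, 30, 40, 50, 60)


@dataclass(frozen=True)
class MotionParams:
    """Kinematic constants of the display.

    Defaults reproduce the experimental display: 200 px/s at 100 Hz (2 px
    per frame), heading-increment circular SD of pi/8 rad, a 268x268 px
    arena, and a 6000 ms trial (1000 ms highlight + 5000 ms tracking).
    """

    speed: float = 200.0  # px / s
    frame_rate: float = 100.0  # Hz
    sigma: float = pi / 8  # rad, SD of per-frame heading change
    arena_px: float = 268.0  # side of the square confinement region
    square_px: float = 32.0
    highlight_ms: float = 1000.0
    track_ms: float = 5000.0
    confine_mode: Literal["centre", "square"] = "centre"
    max_redraws: int = 20

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if not (0 <= self.sigma < pi):
            raise ValueError("sigma must lie in [0, pi)")
        if self.arena_px < self.square_px:
            raise ValueError("arena side must be at least the square size")

    @property
    def step_px(self) -> float:
        """Per-frame displacement magnitude: speed / frame_rate (2 px default)."""
        return self.speed / self.frame_rate

    @property
    def n_frames(self) -> int:
        """Total frames in one trial (highlight + tracking)."""
        return round((self.highlight_ms + self.track_ms) / 1000.0 * self.frame_rate)

    @property
    def half_extent(self) -> float:
        """Largest |coordinate| a square centre may take."""
        if self.confine_mode == "centre":
            return self.arena_px / 2.0
        return (self.arena_px - self.square_px) / 2.0


@dataclass(frozen=True)
class SquareState:
    """Centre position (px) and heading (rad, normalized to [0, 2*pi))."""

    position: tuple[float, float]
    heading: float


def _wrap(theta: np.ndarray | float) -> np.ndarray | float:
    out = np.mod(theta, tau)
    # np.mod can round a tiny negative input up to exactly 2*pi.
    return np.where(out >= tau, 0.0, out)


def step_heading(theta, sigma: float, rng: np.random.Generator):
    """One wrapped-normal heading update: theta + N(0, sigma^2), wrapped.

    Accepts a scalar or an array of headings; draws one increment per
    element.  Sampling a plain normal and wrapping is exact for the wrapped
    normal distribution.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    theta = np.asarray(theta, dtype=float)
    if sigma == 0:
        return _wrap(theta.copy())
    return _wrap(theta + rng.normal(0.0, sigma, size=theta.shape))


def step_batch(
    pos: np.ndarray,
    heading: np.ndarray,
    params: MotionParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance every square one frame; vectorized over any leading shape.

    ``pos`` has shape ``(..., 2)``, ``heading`` shape ``(...,)``.  Returns
    the new (position, heading) arrays.  Confinement: redraw the heading
    increment for violating squares (up to ``params.max_redraws`` times),
    then reflect the heading about each violated wall.
    """
    step = params.step_px
    half = params.half_extent
    shape = heading.shape

    new_heading = step_heading(heading, params.sigma, rng)
    new_pos = pos + step * np.stack([np.cos(new_heading), np.sin(new_heading)], axis=-1)

    # Flat views so the redraw loop touches only the violating subset.
    fpos = pos.reshape(-1, 2)
    fheading = np.asarray(heading, dtype=float).reshape(-1)
    npos = new_pos.reshape(-1, 2)
    nhead = new_heading.reshape(-1)
    bad = np.flatnonzero(np.any(np.abs(npos) > half, axis=-1))
    attempts = 0
    while bad.size and attempts < params.max_redraws:
        redraw = step_heading(fheading[bad], params.sigma, rng)
        cand = fpos[bad] + step * np.stack([np.cos(redraw), np.sin(redraw)], axis=-1)
        nhead[bad] = redraw
        npos[bad] = cand
        bad = bad[np.any(np.abs(cand) > half, axis=-1)]
        attempts += 1

    if bad.size:
        # Reflect about each violated wall; guarantees an inward step since
        # the current centre is inside the arena.
        th = nhead[bad]
        cand = npos[bad]
        th = np.where(np.abs(cand[:, 0]) > half, pi - th, th)
        th = np.where(np.abs(cand[:, 1]) > half, -th, th)
        th = _wrap(th)
        nhead[bad] = th
        npos[bad] = np.clip(
            fpos[bad] + step * np.stack([np.cos(th), np.sin(th)], axis=-1),
            -half, half)  # clip guards against FP grazing only

    return npos.reshape(*shape, 2), nhead.reshape(shape)


def advance(state: SquareState, params: MotionParams, rng: np.random.Generator) -> SquareState:
    """Single-square convenience wrapper around :func:`step_batch`."""
    pos = np.asarray([state.position], dtype=float)
    heading = np.asarray([state.heading], dtype=float)
    new_pos, new_heading = step_batch(pos, heading, params, rng)
    return SquareState(position=(float(new_pos[0, 0]), float(new_pos[0, 1])),
                       heading=float(new_heading[0]))


@dataclass
class TrajectorySet:
    """Per-frame positions/headings of every square in one trial.

    ``positions`` has shape (n_frames, n_squares, 2); ``headings``
    (n_frames, n_squares).  ``target_index`` flags the tracked square.
    """

    positions: np.ndarray
    headings: np.ndarray
    target_index: int
    params: MotionParams = field(default_factory=MotionParams)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_squares(self) -> int:
        return self.positions.shape[1]

    @property
    def target_positions(self) -> np.ndarray:
        return self.positions[:, self.target_index, :]


def init_states(
    n: int, params: MotionParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform initial centres in the arena and uniform initial headings."""
    half = params.half_extent
    pos = rng.uniform(-half, half, size=(n, 2))
    heading = rng.uniform(0.0, tau, size=n)
    return pos, heading


def simulate_trial_motion(
    n: int, params: MotionParams, rng: np.random.Generator
) -> TrajectorySet:
    """Simulate one trial's motion for ``n`` squares.

    Initial positions are uniform over the arena, initial headings uniform
    on the circle; the target square is chosen uniformly.  Group sizes
    outside the standard design are allowed with a warning.
    """
    if n < 1:
        raise ValueError(f"need at least one square, got n={n}")
    if n not in STANDARD_SET_SIZES:
        warnings.warn(f"group size {n} is outside the standard design sizes "
                      f"{STANDARD_SET_SIZES}", stacklevel=2)
    n_frames = params.n_frames
    pos, heading = init_states(n, params, rng)
    target_index = int(rng.integers(n))
    positions = np.empty((n_frames, n, 2))
    headings = np.empty((n_frames, n))
    positions[0], headings[0] = pos, heading
    for f in range(1, n_frames):
        pos, heading = step_batch(pos, heading, params, rng)
        positions[f], headings[f] = pos, heading
    return TrajectorySet(positions=positions, headings=headings,
                         target_index=target_index, params=params)


def trajectories_to_frame(traj: TrajectorySet, trial: int = 0):
    """Long-format export: one row per (frame, square)."""
    import pandas as pd

    n_frames, n_squares = traj.headings.shape
    frames = np.repeat(np.arange(n_frames), n_squares)
    squares = np.tile(np.arange(n_squares), n_frames)
    return pd.DataFrame({
        "trial": trial,
        "frame": frames,
        "square": squares,
        "x": traj.positions[:, :, 0].ravel(),
        "y": traj.positions[:, :, 1].ravel(),
        "heading": traj.headings.ravel(),
        "is_target": squares == traj.target_index,
    })
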