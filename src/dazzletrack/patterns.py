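"""Square colorations: striped gratings and binary noise at two contrast levels.

Every moving square carries a 32x32-pixel luminance texture defined in the
square's *object frame*: the +x axis of the image is the square's heading
axis.  "Parallel" stripes are elongated along the heading (stripe boundaries
perpendicular to +y); "orthogonal" stripes run across it.  Three pattern
kinds exist -- ``parallel``, ``orthogonal`` and ``binary`` noise -- each
rendered with one of two fixed luminance pairs.

Luminances are carried symbolically in cd/m^2; no display-calibration model
is applied.  The two pairs are (0.5, 132.5) for the nominal 100%-contrast
condition and (38, 103) for the nominal 50% condition.  Note the printed
pairs give Michelson contrasts of ~0.992 and ~0.461 rather than literally
1.0 and 0.5, and neither pair averages to the 71.4 cd/m^2 background; the
pairs themselves are treated as ground truth and the percentage labels as
nominal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "LuminancePair",
    "PatternSpec",
    "SQUARE_PX",
    "GRATING_WAVELENGTH_PX",
    "NOISE_BLOCK_PX",
    "BACKGROUND_LUMINANCE",
    "lum_pair_for",
    "michelson_contrast",
    "render_grating",
    "render_binary_noise",
    "render_pattern",
    "pattern_to_csv",
    "pattern_to_png",
]

SQUARE_PX = 32
GRATING_WAVELENGTH_PX = 8
NOISE_BLOCK_PX = 4
#: Mean screen luminance behind the squares, cd/m^2.
BACKGROUND_LUMINANCE = 71.4

PatternKind = Literal["parallel", "orthogonal", "binary"]
ContrastLevel = Literal["high", "low"]

_LUMINANCE_PAIRS = {
    "high": (0.5, 132.5),
    "low": (38.0, 103.0),
}


@dataclass(frozen=True)
class LuminancePair:
    """Dark/light luminance pair in cd/m^2, dark strictly below light."""

    dark: float
    light: float

    def __post_init__(self) -> None:
        if not (0 < self.dark < self.light):
            raise ValueError(
                f"need 0 < dark < light, got dark={self.dark}, light={self.light}"
            )

    @property
    def michelson(self) -> float:
        return (self.light - self.dark) / (self.light + self.dark)


@dataclass(frozen=True)
class PatternSpec:
    """Specification of one square's surface pattern.

    ``wavelength_px`` applies to gratings only, ``block_px`` to noise only.
    ``phase`` is 0 or 180 (degrees): phase 180 is the complement image of
    phase 0.
    """

    kind: PatternKind
    lum_pair: LuminancePair
    wavelength_px: int = GRATING_WAVELENGTH_PX
    block_px: int = NOISE_BLOCK_PX
    phase: int = 0
    size_px: int = SQUARE_PX

    def __post_init__(self) -> None:
        if self.kind not in ("parallel", "orthogonal", "binary"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.phase not in (0, 180):
            raise ValueError(f"phase must be 0 or 180 degrees, got {self.phase}")
        if self.kind != "binary" and self.size_px % self.wavelength_px:
            raise ValueError("square size must be a multiple of the wavelength")
        if self.kind == "binary" and self.size_px % self.block_px:
            raise ValueError("square size must be a multiple of the block size")


def lum_pair_for(contrast_level: str) -> LuminancePair:
    """Return the fixed luminance pair for a contrast level ('high' or 'low')."""
    try:
        dark, light = _LUMINANCE_PAIRS[contrast_level]
    except KeyError:
        raise ValueError(
            f"unknown contrast level {contrast_level!r}; expected one of "
            f"{sorted(_LUMINANCE_PAIRS)}"
        ) from None
    return LuminancePair(dark, light)


def michelson_contrast(pair: LuminancePair) -> float:
    """(Lmax - Lmin) / (Lmax + Lmin) of a two-level pattern."""
    return pair.michelson


def render_grating(spec: PatternSpec) -> np.ndarray:
    """Render a square-wave grating in the object frame.

    The returned array is ``(size, size)`` with rows indexing +y and columns
    +x (heading axis).  Parallel stripes modulate along +y (stripes elongated
    along the heading); orthogonal stripes modulate along +x.  The duty cycle
    is 50%: half a wavelength dark, half light.
    """
    if spec.kind == "binary":
        raise ValueError("render_grating requires a grating kind, got 'binary'")
    n, wl = spec.size_px, spec.wavelength_px
    coord = np.arange(n)
    # Square wave: first half-wavelength dark at phase 0.
    wave = (coord % wl) >= wl // 2  # True -> light
    if spec.phase == 180:
        wave = ~wave
    if spec.kind == "parallel":
        img = np.broadcast_to(wave[:, None], (n, n))
    else:  # orthogonal: stripes across the heading, modulation along +x
        img = np.broadcast_to(wave[None, :], (n, n))
    return np.where(img, spec.lum_pair.light, spec.lum_pair.dark)


def render_binary_noise(spec: PatternSpec, rng: np.random.Generator) -> np.ndarray:
    """Render binary block noise: each block dark or light with probability 1/2."""
    if spec.kind != "binary":
        raise ValueError(f"render_binary_noise requires kind 'binary', got {spec.kind!r}")
    nb = spec.size_px // spec.block_px
    blocks = rng.random((nb, nb)) < 0.5  # True -> dark
    img = np.where(blocks, spec.lum_pair.dark, spec.lum_pair.light)
    return np.repeat(np.repeat(img, spec.block_px, axis=0), spec.block_px, axis=1)


def render_pattern(spec: PatternSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Dispatch to the appropriate renderer; noise requires an rng."""
    if spec.kind == "binary":
        if rng is None:
            raise ValueError("binary noise rendering requires an rng")
        return render_binary_noise(spec, rng)
    return render_grating(spec)


def pattern_to_csv(img: np.ndarray, path) -> None:
    np.savetxt(path, img, delimiter=",", fmt="%.6g")


def pattern_to_png(img: np.ndarray, path, vmax: float = 132.5) -> None:
    """Write a greyscale PNG for visual inspection (luminance mapped linearly)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(2, 2), dpi=100)
    ax.imshow(img, cmap="gray", vmin=0.0, vmax=vmax, origin="lower", interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)
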