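"""Render the six square colorations used on the moving targets.

Three pattern kinds (stripes parallel to the heading, stripes orthogonal
to it, and 4x4-px binary noise), each at the maximal-contrast luminance
pair (0.5 / 132.5 cd m^-2) and the lower-contrast pair (38 / 103).
Writes one CSV grid and one PNG per condition under results/patterns/,
and prints each pattern's Michelson contrast and mean luminance.
"""

from pathlib import Path

import numpy as np

from dazzletrack.patterns import (
    BACKGROUND_LUMINANCE,
    PatternSpec,
    lum_pair_for,
    pattern_to_csv,
    pattern_to_png,
    render_pattern,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "patterns"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    print(f"background luminance: {BACKGROUND_LUMINANCE} cd/m^2")
    for kind in ("parallel", "orthogonal", "binary"):
        for level in ("high", "low"):
            pair = lum_pair_for(level)
            img = render_pattern(PatternSpec(kind=kind, lum_pair=pair), rng)
            stem = OUT / f"{kind}_{level}"
            pattern_to_csv(img, f"{stem}.csv")
            pattern_to_png(img, f"{stem}.png")
            print(f"{kind:>10} / {level:<4} contrast: Michelson "
                  f"{pair.michelson:.4f}, mean {img.mean():6.2f} cd/m^2 "
                  f"-> {stem.name}.csv/.png")
    print(f"\nNote: the 'high'/'low' labels are nominal (100%/50%); the "
          f"printed pairs give Michelson contrasts of ~0.992 and ~0.461.")


if __name__ == "__main__":
    main()
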