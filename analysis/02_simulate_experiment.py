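"""Simulate the full tracking experiment with the synthetic observer.

Fourteen synthetic participants each complete 4 practice trials plus 336
trials (6 randomly ordered coloration x contrast blocks, 7 group sizes x 8
repetitions shuffled within block).  Squares perform a confined correlated
random walk (2 px per 10 ms frame, heading-change SD pi/8) in a 268x268 px
arena; the observer tracks the cued square with lag, motor noise and
density-dependent target swaps whose rate is scaled by condition.  The
per-trial response is the mean cursor-target distance over the final
4000 ms.  Writes results/trials.csv and prints the marginal means.
"""

from pathlib import Path

import numpy as np

from dazzletrack.io import write_trials
from dazzletrack.observer import ObserverParams, generate_dataset
from dazzletrack.session import SessionDesign

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    trials = generate_dataset(SessionDesign(), ObserverParams(), 14, rng)
    write_trials(trials, OUT / "trials.csv")
    analysed = trials[~trials["is_practice"]]
    print(f"seed {seed}: {len(trials)} rows "
          f"({int(trials['is_practice'].sum())} practice) -> results/trials.csv")
    print("\nmean tracking error (px) by group size:")
    print(analysed.groupby("set_size")["mean_error_px"].mean().round(2).to_string())
    print("\nmean tracking error (px) by coloration:")
    print(analysed.groupby("coloration")["mean_error_px"].mean().round(2).to_string())
    print("\nmean tracking error (px) by contrast:")
    print(analysed.groupby("contrast")["mean_error_px"].mean().round(2).to_string())
    print("\nErrors rise with group size (confusion effect) and are ordered "
          "parallel > orthogonal > binary; contrast makes little difference.")


if __name__ == "__main__":
    main()
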