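# dazzletrack

Simulation and mixed-model analysis of target tracking among
dazzle-patterned distractors.

## The problem

When concealment fails, high-contrast repetitive patterns ("motion
dazzle camouflage") may degrade a predator's ability to track a moving
target — especially in groups, where the *confusion effect* makes
targeting harder as group size grows.  A standard laboratory probe of
this idea has an observer track one cued square among 1–60 identical
distractors performing a confined correlated random walk, with the
squares' surface patterns (stripes parallel or orthogonal to the
heading, or binary noise, at maximal or reduced contrast) as the
experimental treatments and the mean cursor-to-target distance as the
response.

`dazzletrack` reimplements that paradigm end to end as a tested
pipeline for researchers in visual ecology and psychophysics:

* **stimuli** (`patterns`) — 32 x 32 px object-frame textures: 8 px
  square-wave gratings and 4 x 4 px binary noise at the two luminance
  pairs (0.5, 132.5) and (38, 103) cd/m²;
* **motion** (`kinematics`) — confined correlated random walk, 2 px per
  10 ms frame, wrapped-normal heading increments with SD π/8, centres
  confined to a 268 x 268 px arena;
* **a synthetic observer** (`observer`) — an explicitly artificial
  stand-in for human participants that tracks with lag and motor noise
  and occasionally swaps its believed target to a nearby distractor,
  producing confusion-effect data with a built-in condition ordering;
* **design & scoring** (`session`, `metrics`) — 6 blocks x 7 group
  sizes x 8 repetitions = 336 trials per participant; mean
  cursor-target distance over the final 4000 ms; participant x cell
  means, log-transformed;
* **inference** (`stats`) — random-intercept linear mixed models fitted
  by profiled maximum likelihood,

      y = Xβ + Zb + ε,  b ~ N(0, σ²_b I_q),  ε ~ N(0, σ²_e I_n),

  compared in a backward ladder of likelihood-ratio χ² tests (quadratic
  vs linear group-size polynomial, then each interaction, then each
  main effect), with AIC = −2ℓ + 2k, Tukey-type all-pairwise coloration
  contrasts (single-step joint-normal adjustment), and Cousineau–Morey
  within-subject 95 % CIs;
* **io & CLI** (`io`, `cli`) — canonical CSV trial tables, a
  `ColumnMap` adapter for external datasets, and a `dazzletrack`
  command with `simulate`, `analyze`, `reproduce` and `render`
  subcommands.

See `docs/methods.md` for the full model description, parameter
defaults and numerical choices.

## Worked example

```sh
python analysis/02_simulate_experiment.py   # writes results/trials.csv
python analysis/03_fit_model_ladder.py      # ladder of chi-square tests
python analysis/04_posthoc_and_figures.py   # contrasts, CIs, figures
```

With the default seed the simulation prints mean tracking errors rising
from 18.6 px at group size 1 to 74.2 px at 60 (the confusion effect),
ordered parallel (54.5) > orthogonal (50.7) > binary (43.1) px, with a
negligible contrast difference (49.3 vs 49.6 px).  The ladder then
reports:

```
                     label    chi2  df          p  aic_full  aic_reduced
number quadratic vs linear  94.633   6  3.296e-18    260.38       343.01
     three-way interaction   0.460   4     0.9773    260.38       252.84
     coloration x contrast   1.193   2     0.5507    252.84       250.03
         contrast x number   0.022   2     0.9889    250.03       246.06
       coloration x number   6.902   4     0.1412    246.06       244.96
    coloration main effect  58.471   2   2.01e-13    244.96       299.43
        number main effect 698.229   2 2.407e-152    244.96       939.19
      contrast main effect   0.149   1     0.6991    244.96       243.11
```

i.e. tracking error depends strongly and curvilinearly on group size
and on coloration, not on contrast, with no significant interactions —
and the post hoc contrasts recover the injected ordering:

```
orthogonal - binary      estimate +0.1623  z +5.527  adjusted p 6.222e-08
parallel - binary        estimate +0.2227  z +7.586  adjusted p 4.741e-14
parallel - orthogonal    estimate +0.0605  z +2.059  adjusted p 0.09855
```

The same pipeline runs from the shell:

```sh
dazzletrack reproduce --seed 1 --out-dir results --figures
dazzletrack analyze --in my_trials.txt --column-map map.yaml
```

`analyze` accepts any delimited trial table; non-canonical column names
and factor labels are declared in a YAML `ColumnMap` rather than
guessed.

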