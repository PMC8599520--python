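# ramtrack

Bitmap-based tracking and behavioral scoring for rodent radial-arm-maze
(RAM) tests.

The eight-arm radial maze is a standard assay of spatial memory in rats:
food is placed at the distal ends of a subset of "baited" arms and the
animal's visits are scored — a re-entry into an already-visited arm is a
*working (short-term) memory error*, the first entry into a never-baited arm
is a *reference (long-term) memory error*, and the *latency* is the time
until every baited arm has been emptied.  `ramtrack` automates both halves
of the experiment from overhead infrared video:

1. **Localization.** Each frame is converted to grayscale
   (`0.299·R + 0.589·G + 0.114·B`), binarized at a strict threshold of 127
   (the rat appears bright under IR illumination on a dark background), and
   duplicated.  One copy is intersected with the filled maze-footprint
   *mask* and opened with a 5×5 all-ones structuring element
   (`A∘B = (A⊖B)⊕B`); the other is opened directly; their intersection
   yields the candidate components.  A single component is the rat; among
   several, the **largest component whose centroid lies inside the maze**
   wins — droppings smaller than the structuring element are erased by the
   opening, anything outside the footprint is erased by the mask, and the
   in-maze residue of an intruding experimenter's leg is smaller than the
   animal.  The centroid is logged every 0.05 s.
2. **Scoring.** A state machine watches the distance from the tracked
   center to each arm's proximal entry line (with a side-of-line hysteresis)
   to detect entries and exits, clears an arm's food flag when the animal
   reaches the distal food zone, and accumulates the error counts and
   latency.  Trajectory metrics complete the report: path length (sum of
   consecutive dot distances), average speed, percentage of time in the
   platform / baited / non-baited arms, stillness ("S") spots, and a
   89-zone occupancy histogram (each arm split into ten 70 cm² segments,
   the platform into nine ≈70 cm² pieces).

A fully ground-truthed synthetic scene generator (moving elliptical rat,
persistent dropping spots, out-of-maze clutter, leg/shoe-like intruder)
makes the entire pipeline testable without any real recordings.

## Worked example

`examples/02_score_session.py` scripts a session in which the animal visits
baited arm 4, baited arm 2, never-baited arm 7, re-enters arm 4, then
empties arms 6 and 8:

```
arm sequence       : (4, 2, 7, 4, 6, 8)
latency            : 87.8 s  (all baited arms emptied)
working-memory err : 1  (re-entry into arm 4)
reference-mem err  : 1  (first entry into never-baited arm 7)
path length        : 9.56 m
average speed      : 9.8 cm/s
dwell platform/baited/non-baited : 13.6% / 72.0% / 14.4%
S spots            : 6 episodes, 21.2 s total stillness
```

The other examples localize the rat in a single noisy frame
(`01_localize_one_frame.py`, localization error 0.00 px on the synthetic
frame) and measure robustness on short Case-1/Case-2 analogs
(`03_robustness_cases.py`).

A thin CLI wraps the same library calls:

```sh
ramtrack simulate --case 1 --duration 30 --outdir scratch/sim   # frames + truth
ramtrack track --frames scratch/sim/frames --fps 10 --outdir scratch/out
ramtrack evaluate --trajectory scratch/out/trajectory.csv --truth scratch/sim/truth.csv
ramtrack run --case 2 --seed 1 --duration 60 --outdir scratch/run  # end to end
```

`track` writes `trajectory.csv`, `summary.csv`/`summary.xlsx`, a trajectory
bitmap and a zone-occupancy heatmap.

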