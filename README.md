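# botmetrics

Quantitative analysis of motile ciliated spheroids ("bots"): multicellular
constructs, tens to hundreds of µm across, that self-assemble from human
airway epithelial cells and swim by surface cilia.  Researchers tracking
such constructs in timelapse video and imaging them in confocal Z-stacks
face four recurring quantification problems, and this package implements a
tested, reusable pipeline for each:

1. **Behavioral ethogram** — from tracked 2D trajectories, per-position
   kinematics and two block-level movement indices:
   straightness `S = 1 − CV(θ)` (circular variance of the headings;
   1 = perfect line) and gyration `G = 1 − CV(ω)/CV(ω ∪ −ω)` (angular
   speeds pooled with their additive inverses; 1 = perfect circle).
   Inactive blocks are gated out by a two-component gamma mixture on a
   dead-reckoning prediction error; active blocks are clustered in the
   (S, G) plane by cross-entropy clustering, and transitions between
   consecutive blocks give a Markov-chain ethogram.
2. **3D morphometrics** — eight indices per bot from binarized body/cilia
   point clouds (cilia points, noise points, max radius, aspect, shape
   smoothness, cilia/area, polarity `‖Σvᵢ‖/Σ‖vᵢ‖`, and a 1NN-distance
   KS homogeneity score), then PCA + Ward.D2 morphotype clustering,
   bootstrap loading ranks and Fisher exact morphotype–behavior overlap
   tests.
3. **Bilateral symmetry** — hemisphere counts, an unsquared Chamfer
   distance between projected cilia hemispheres, and a body KS statistic,
   evaluated at the movement axis and at Rodrigues-rotated control axes.
4. **Scratch traversal and gap closure** — disc–tissue contact fraction,
   rotational tendency, scratch-trajectory similarity, the track filters
   and OLS contact models, and six-ROI pixel-density comparison around a
   bridge spanning a scratch.

A seeded synthetic-data generator (`botmetrics.synthgen`) produces
trajectories of every movement class, spheroid clouds with controlled
cilia polarization and noise, and scratch/bridge scenes — each with ground
truth — so the whole stack is exercised without any external data.

## Worked example

```python
import numpy as np
from botmetrics import synthgen as sg, kinematics as km, ethogram as eg, morpho

# --- behavior: simulate 12 bots, classify their 30-s blocks -------------
rng = np.random.default_rng(0)
blocks = []
for cls in ("circular", "linear", "inactive"):
    for i in range(4):
        traj, _ = sg.simulate_trajectory(
            sg.TrajectorySpec(cls, duration_s=900, seed=int(rng.integers(2**31))))
        traj.bot_id = f"{cls}-{i}"
        blocks += km.segment_blocks(traj)

table = km.block_table(blocks)
table, summary = eg.classify_blocks(table, k_init=4, seed=0)
print(summary["n_active"], summary["n_inactive"])   # 240 120
print(summary["markov"].to_frame().round(3))
#           circular  linear
# circular       1.0     0.0
# linear         0.0     1.0

# --- morphology: one polarized bot through the eight-index pipeline ----
cloud = sg.generate_bot_cloud(sg.BotCloudSpec(
    cilia_mode="polarized", polar_concentration=20, noise_fraction=0.1,
    n_cilia=300, seed=1))
print(morpho.compute_morpho_indices(cloud))
```

The run gates all 120 jitter blocks as inactive and classifies every
active block with its generating class, so the estimated transition matrix
is the identity — pure circular and linear bots never interconvert.  The
morphometric record for the polarized bot reads (rounded): `cilia_points
63`, `noise_points 30` (the generator placed 30 isolated cilia),
`max_radius 75.0`, `aspect 1.0`, `shape_smoothness 0.979`, `polarity 0.83`
(a von Mises–Fisher κ = 20 patch concentrates the cilia at one pole) and
`homogeneity 0.26` (strongly non-uniform coverage).

A `botmetrics` command-line tool chains the stages on a seeded synthetic
bundle (`botmetrics all --seed 1 --out run1/`); see `botmetrics --help`.

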