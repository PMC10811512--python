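# Methods

`botmetrics` quantifies the behavior and morphology of ciliated multicellular
spheroids ("bots", 30–500 µm) that self-propel on surfaces, and their
interaction with scratch-wounded tissue monolayers.  This note records the
models, the parameters that matter, and the design choices made where the
procedure was genuinely open.

## Movement indices and the ethogram

Tracked positions (2.5-s sampling, 5-h timelapses typical) yield per-position
kinematics: the step distance, the linear speed `v = step/dt`, the heading
`θ` as the atan2 direction of the previous→current displacement, and the
angular speed `ω` as the wrapped difference of successive headings divided by
the elapsed time between the two positions.  Headings of zero-length steps
are undefined and propagate as NaN — never as 0, which would bias the
circular statistics.

Analysis operates on non-overlapping 30-s blocks (12 samples); blocks with a
missing timestamp are dropped, and samples within one bot length (default
100 µm) of the arena boundary can be excluded before blocking.  Per block:

* **Straightness** `S = 1 − CV(θ)` where `CV` is the circular variance
  (1 − mean resultant length).  `S = 1` for a straight line.
* **Gyration** `G = 1 − CV(ω) / CV(ω ∪ −ω)`, with the angular speeds read as
  angles in radians.  Pooling with the additive inverses brings the turn
  magnitude into the denominator: constant nonzero turning gives `G = 1`
  (perfect circle), sign-balanced or zero turning gives `G ≈ 0`.  When
  `CV(ω ∪ −ω) = 0` (no turning at all) the index is undefined, not 1.
  Feeding raw rad/s values to the circular variance is safe at 2.5-s
  sampling because per-step heading changes are bounded by π, keeping
  `|ω| < π/2.5` well inside one period.
* **Normalized prediction error** `E`: at each interior position a
  constant-speed constant-turn dead-reckoning step (`θ' = θ + ω·dt`,
  displacement `v·dt`) predicts the next position; the summed prediction
  error is divided by the block path length.  This predictor is exact on
  noiseless lines *and* circles (the predicted chord equals the actual
  chord of a constant-turn walk), so `E` isolates unpredictability rather
  than curvature.  Stationary blocks (path length below 1e−6 µm) return a
  sentinel (default 10) with a flag rather than dividing by zero.

**Activity gate.**  A two-component gamma mixture is fit to the block errors
by EM (weighted gamma MLE via the digamma equation; method-of-moments
initialization on a quantile split; 20 restarts; seeded).  Blocks assigned
by posterior to the higher-mean component are inactive: an inactive bot
jitters, so its prediction error is on the order of its path length, while
an active bot moves predictably.  Degenerate (zero-variance) inputs raise
and should be gated with a fixed threshold instead.

**Clustering.**  Active blocks are clustered in the (S, G) plane by
cross-entropy clustering: hard assignment under the per-cluster Gaussian
cost `−ln p_k + ½[(x−µ_k)ᵀΣ_k⁻¹(x−µ_k) + ln det Σ_k + d ln 2π]`, with
clusters eliminated when their weight falls below `card_min` (default 5%),
so the surviving count can be below `k_init` (default 6).  Ten seeded
restarts keep the lowest total cost.  A Gaussian-mixture fallback is
available behind `method="gaussian-mixture"`.  Clusters are mapped to the
named movement classes by nearest prototype corner of the behavior plane —
circular (0, 1), linear (1, 0), curvilinear (1, 1) — which also realizes
the merge of near-duplicate clusters into their prototypes; explicit merge
maps with before/after intra-cluster mean pairwise distance (the "average
dissimilarity") are supported.  Transition proportions between consecutive
blocks form the Markov ethogram; transitions are never counted across bot
boundaries or across inactive/excluded gaps, and states without outgoing
transitions keep a flagged NaN row.

## Morphometrics

Eight indices per bot from binarized 3D body and cilia point clouds (µm;
z-step 3 µm typical):

1. **Cilia points** — each cilium is projected to its nearest body point;
   the count of unique body points hit.
2. **Noise points** — DBSCAN on the projected cilia (duplicates keep their
   multiplicity); points labeled noise.  Defaults: `eps` = 3.5× the median
   1NN distance of the body points — the projection snaps cilia to the body
   grid, so the clustering radius must resolve that grid, not the raw
   cilia spacing — and `min_pts = 4`.  Both are exposed in the config.
3. **Max radius** and 4. **aspect** — largest semi-axis and largest/smallest
   ratio of the minimum-volume enclosing ellipsoid, computed by Khachiyan
   coordinate ascent with Wolfe–Atwood away steps (ε-primality tolerance
   1e−7, post-hoc inflation guarantees containment).  Affinely degenerate
   clouds raise with a jitter recommendation.
5. **Shape smoothness** — alpha-hull volume / spanning-ellipsoid volume.
6. **Cilia/area** — cilia points divided by the alpha-hull surface area.
7. **Polarity** — `‖Σ vᵢ‖ / Σ‖vᵢ‖` for the vectors from the body center
   (area-weighted centroid of the alpha-hull triangles) to each cilium.
   The defining sentence admits a second reading (mean resultant of unit
   vectors); the resultant-length-ratio reading is used because it gives
   the 0–1 polarization semantics the indices require.
8. **Homogeneity** — `1 − D` of the two-sample KS test between observed
   cilia 1NN distances and those of an equal-count area-uniform draw on
   the alpha surface (optionally averaged over several reference draws).

The alpha complex keeps Delaunay tetrahedra with circumradius ≤ alpha; the
boundary is the set of faces owned by exactly one kept tetrahedron.  The
default alpha is data-driven: the smallest circumradius threshold whose
complex forms a single connected component covering ≥99% of the points,
times a 5% margin.  A fixed alpha tied to point spacing is unusable for
surface-sampled clouds — points on a common sphere make every tetrahedron's
circumradius equal the sphere radius — and is kept only as a config option
for volumetric masks.  A consequence of surface sampling is that the alpha
hull cannot resolve concavities much smaller than the enclosed-ball scale;
shape smoothness still separates bumpy from smooth bodies because radial
lobes inflate the spanning ellipsoid faster than the hull.

Binarization of intensity volumes: the body channel is logistic-transformed
(sigmoid of standardized intensities), median-filtered to estimate the
noise-free signal, and thresholded at background + `snr_factor` (default 5)
times the residual noise sd; the cilia channel uses the Rényi-entropy
automatic threshold (orders ½, 1, 2 combined with the classic weighting
rule).  Dense voxel masks can be reduced to per-slice concave-hull outlines
(shapely `concave_hull`, ratio 0.4 by default) before the 3D steps.

**Morphotypes.**  The index table is z-scaled; PCA (centered and scaled)
provides scores and loadings for inspection; Ward.D2 agglomeration (scipy's
`ward` on the scaled table — equivalent to R's Ward.D2 on Euclidean
distances) is cut at `k = 3` by default, with the silhouette reported so
other k remain visible.  Clustering on PC scores is available but the
scaled table is the default, since the two differ only by the PCA rotation
when all components are kept.  Loading stability is assessed by
bootstrapping rows (default 10 draws of 250), recording absolute loadings
(the PC sign is arbitrary), and ranking variables by the chain rule
relative to the highest contributor: a variable co-ranks 1 iff its 95%
t-interval overlaps the top variable's interval.  Morphotype–behavior
overlap uses 2×2 Fisher exact tests per cluster pair (non-movers vs movers;
circular vs linear counts), skipping comparisons with an empty margin.

## Bilateral symmetry

The movement axis (center, front, back anchor points) defines a vertical
symmetry plane containing the axis and the imaging z-axis.  Hemisphere
membership is the sign of `normal · (p − center)` (tie tolerance 1e−9 µm;
on-plane points split evenly with an odd remainder reported).  Asymmetry
scores: the count difference `diff` and ratio `difftot`; the modified
Chamfer distance — project all cilia onto the plane and sum the mean (or
median) unsquared nearest-neighbor distances A→B and B→A (zero for a
mirror-symmetric pattern); and the body KS D between hemisphere
center-distance distributions.  The 2D Chamfer variant maps the projected
points to 2D through a PCA rotation; since the projection is already
rank-2 this preserves distances exactly and matches the 3D value — both
modes are kept for interface fidelity.  Control planes rotate the normal
by Rodrigues' formula about the z-axis through the center (45/90/135°);
the z-axis is chosen as the rotation axis so every control plane stays
vertical, as the three-point construction implies.  The per-bot contrast
(asymmetry at ≈90° minus at the movement axis) is tested against zero per
movement class with a two-sided one-sample t-test and one-sided Wilcoxon
signed-rank tests ('greater' for circulars, 'less' for linears) — the
signed-rank form is used because a rank-sum test has no paired version.

## Scratch traversal and gap closure

The bot is modeled as a disc of its tracked radius; `proportion_on_tissue`
is the raster overlap of the disc with the tissue mask, averaged over
frames (per-frame values are also emitted).  `rotational_tendency` is the
gyration index of the whole track.  `scratch_similarity` pairs each track
heading with the smoothed heading of the edge segment at the foot of the
perpendicular from the step midpoint (the midpoint lies on the segment the
heading describes); both unwrapped series enter a Pearson correlation, and
the larger absolute value over the two edges is reported.  Zero-variance
series (straight channel, straight track) yield a flagged NaN rather than
0, so such scenes are excluded explicitly.  Track filters: rotational
tendency within [0.33, 0.7], nonzero scratch contact, viable tracking;
every exclusion is logged with its rule.  OLS models relate on-tissue
proportion to rotational tendency and to mean speed, and similarity to a
quadratic in rotational tendency; each report includes a residual-vs-fitted
table and a quadratic residual-curvature p-value so the U-shape that
motivates the quadratic model is inspectable.

Gap-closure density analysis: six ROI boxes the size of the bridge box —
above/below at one vertical bridge length, adjacent at one horizontal
bridge length into the scratch, far one bridge length beyond adjacent —
with the horizontal boxes shifted vertically to overlay the scratch band,
and any box leaving the image raising an error naming the region.  A
smaller bridge length may be passed when the image cannot fit full-length
offsets.  Foreground proportions are compared with Welch t-tests treating
ROI pixels as Bernoulli samples (equivalent to a two-proportion z-test);
with replicate bridge images the per-image proportions could be tested
instead, but single-image pixel-level tests are what the desk-scale
synthetic scenes exercise.  Images are auto-thresholded with Otsu, with a
manual override.

## Synthetic data

The generator provides every input with known ground truth; all generators
are pure functions of their spec (seed included).

* **Trajectories** — constant-speed constant-turn walks with per-step
  Gaussian heading noise.  Presets: circular 10 µm/s at 0.35 rad/s (more
  than one full turn per 30-s block), linear 25 µm/s with no systematic
  turn, curvilinear 18 µm/s at 0.08 rad/s (a gentle arc), speeds inside
  the 5–50 µm/s range typical of these bots.  The inactive class is
  isotropic positional jitter (0.3 µm/step), two orders of magnitude below
  a bot length per block, so the activity gate is separable by design.
  Eclectic bots switch regime between the three active presets exactly at
  block boundaries, driven by a row-stochastic switch matrix (sticky
  default), and the emitted truth carries the per-block class labels.
* **Spheroid clouds** — body points uniform on a radially perturbed
  ellipsoid surface (smooth random lobes, relative amplitude
  `bump_amplitude`); cilia placed in small patches (parents uniform or von
  Mises–Fisher around a random pole — vMF being the standard unimodal
  directional law; members scattered 0.06 rad) because real cilia appear
  in patches, not as independent points.  A `noise_fraction` of cilia are
  isolated singletons rejection-sampled at least 3 body-spacings from any
  patch cilium and 2 from each other, which places them beyond the
  data-driven DBSCAN radius; the truth records their indices and the pole.
  Axis anchors (center, front at +x, back at −x) support the symmetry
  pipeline.  At high noise fractions (≳0.3) the sphere becomes crowded and
  the realized isolation degrades gracefully (counts saturate below the
  nominal value); the monotonicity guarantees hold on the 0.05–0.3 range
  used in the tests.
* **Scratch scenes** — sinusoid-plus-random-walk edges bounding a channel
  (400–1000 µm widths typical), binary tissue mask, and a bot track:
  `midline` (no contact), `trace_edge` (exact copy of the upper edge), or
  `follow` — a heading walk turning ±0.35 rad/s with the positive-turn
  probability set so the track's gyration approximates `follow_gyration`
  (the mapping `G ≈ (2q−1)²` is exact for clean ±ω steps and attenuated by
  the weak steering that keeps the bot near the wall; the realized value
  is monotone in the request).  Bridge scenes add a Bernoulli pixel image
  with known native/scratch/closure densities, the bridge box, and the
  scratch band, with tall margins so all six ROIs fit.

What the generator does **not** emulate: tracking errors (identity swaps,
dropouts), optical artifacts, per-cilium structure (length, beat), bots
that roll (the symmetry anchors assume a stable orientation), and deformable
contact with the scratch wall.  Passing tests therefore demonstrate that
the pipeline recovers the constructs it defines under realistic geometry
and noise — not that it is robust to tracker failure modes, which the
original workflow handled by manual correction upstream.

## Problem sizes and numerics

The test suite and the reproduction script use desk-scale problem sizes
chosen to keep the statistical checks well-powered: behavioral recovery
uses 200 bots (40 per class) at 100 blocks each (≈20k blocks; binomial
standard error per Markov entry < 0.01), morphotype recovery 3×40 clouds
of ~600 body points, and the parameter sweeps 20 seeds per level.  Key
tolerances: MVEE ε = 1e−7 (1e−9 in oracle tests); alpha auto-selection
margin 5%; EM convergence 1e−8 relative log-likelihood; CEC cluster floor
5%; hemisphere tie tolerance 1e−9 µm.  All stochastic stages take explicit
seeds and reproduce bit-for-bit.
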