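# Methods

This note documents the models, estimators, defaults, and known limitations
behind `mitomotility`.  Everything stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted from external data.

## The measurement problem

Axonal mitochondria are transported by kinesin and dynein along
microtubules; most are stationary at any moment and a ~10% minority moves at
~0.1–0.25 μm/s, anterograde (away from the soma) or retrograde (toward it).
Three complementary readouts quantify this:

1. **High-content tracking** of fields containing many axons: each detected
   mitochondrion is linked into a track and scored by its *integrated
   distance* (the sum of all frame-to-frame steps, as opposed to the net
   start-to-end displacement).  Per-well distance distributions feed
   screening statistics.
2. **Kymograph analysis** of a single identified axon: per-mitochondrion
   traces in the arc-length coordinate give percent motile per direction,
   directional run velocities, and density per μm.
3. **Temporal pixel variance** for cells whose mitochondria form a
   reticulum: no per-organelle tracking is possible, so the variance of each
   pixel's binarized occupancy serves as a bulk motility proxy.

## Synthetic data model

The simulator is the package's ground-truth instrument: every estimator is
validated against movies whose per-particle states are known exactly.

**Kinetics.**  A particle is either stationary for the whole movie or motile
with a fixed direction and a constant run speed drawn from
Normal(v_mean, v_sd) truncated at zero.  Motile particles alternate between
moving and paused states in a two-state Markov chain with stationary pause
probability `p_pause` (default 0.10) and geometric pause durations of mean
`mean_pause_frames` (default 4 frames).  Published run/pause kinetics for
axonal mitochondria are not standardised; the Markov chain is the simplest
process that reproduces percent-motile and run-velocity readouts, and no
conclusion here depends on its finer structure.  Stationary particles jitter
with i.i.d. sub-resolution displacements (SD 0.3 px, clipped at 3 SD) around
a fixed anchor.

**Imaging regimes.**  Defaults encode the two experimental geometries:

| parameter | single axon | screening field |
|---|---|---|
| field | 64×448 px | 256×256 px |
| pixel size | 0.2 μm/px | 0.3 μm/px |
| frames | 360 @ 2 Hz (3 min) | 30 @ 1 frame/s |
| axons | 1 (~85 μm) | 10 random chords |
| particles/axon | 8 (~0.09/μm) | 8 |
| velocities | 0.10 antero / 0.14 retro μm/s | 0.15 μm/s |

Axon-regime velocities are control-condition run speeds; the field regime
uses the mid-range of typical axonal velocities.  Particle density matches
the ~0.08–0.1 mitochondria/μm seen in cortical axons.  Particles are
rendered as isotropic Gaussian PSFs (σ 1.2 px, 800 photons) over a constant
background (20 counts) with Poisson shot noise only — at these photon counts
camera read noise is a second-order effect for centroid estimators.  The
peak SNR is ≈8.

**Reticulum movies** render a random tubular network (8 branches, 2 px tube
radius) whose branches each translate along a random direction at a
configurable rate, reflecting at a ±10 px excursion so the cell stays in the
field over a 3-minute movie.  Ground truth is the noise-free binary
occupancy of every pixel in every frame.

**What the simulator does not emulate:** photobleaching, focus drift, 3D
optics, mitochondrial fission/fusion, shape heterogeneity, and
motion-dependent appearance.  Passing tests therefore demonstrate estimator
correctness under idealised optics and kinetics, not robustness to every
artifact of real recordings.

## Tracking

Detection is a difference-of-Gaussians band-pass (scales 1 and 8 px)
followed by Otsu thresholding, floored at median + 4 robust SD so pure-noise
frames yield zero detections; connected components smaller than 3 px² are
discarded and centers are intensity-weighted centroids (sub-pixel, adequate
at screening magnification — Gaussian fitting would gain little at SNR ≈ 8).

Linking is optimal bipartite assignment (Hungarian) per frame pair under a
distance gate of 1 μm per elapsed frame, with gaps of up to 2 missing frames
bridged at a proportionally wider gate.  The padded cost matrix prices
non-assignment just above the gate, so any feasible link is preferred over
opening a new track.  Detections are processed in sorted (y, x) order, which
makes the track partition independent of detector output order.  On
few-particle movies the partition equals an exhaustive minimum-cost
matching oracle exactly.

**Motility threshold.**  A track is motile when its net displacement over
the movie is ≥ 2 μm.  At 0.1–0.25 μm/s over the 30–180 s imaging windows a
directed run covers 3–45 μm while stationary jitter nets well under 0.5 μm,
so the threshold sits in a wide separation valley; it is configurable.

**Integrated distance and the noise floor.**  Summing raw frame-to-frame
steps counts every localisation error as movement, which inflates the
apparent path length of stationary particles (the inflation per frame is
E|ε| ≈ 0.8·σ_step).  `integrated_distance` therefore accepts a moving-average
`smooth_window`; the raw sum (window 1) is the definition and the default,
while field and well summaries use window 5, which suppresses the stationary
noise floor by ~5× and biases directed runs by <2%.  With this convention
per-motile-track path lengths match ground truth to a median error of ~4–5%
at the field regime; individual slow movers (run speed near the noise floor)
can deviate by 20–30%.

**Field summary.**  The mean integrated distance is reported over motile
tracks only (an option computes it over all tracks).  Track fragments
spanning less than half the movie are excluded from summaries as broken
links.  Percent motile is recovered within ~1–1.5 points (mean absolute
error over 10 fields) at motile fractions of 0–0.2.

## Screening statistics

Per-well particle distance distributions are compared with the pooled
vehicle (DMSO) distribution via the two-sample Kolmogorov–Smirnov statistic
(asymptotic p-value).  Each per-well statistic x is standardised with the
plate formula Z = (x − μ)/σ, where μ and σ are the mean and sample SD of the
vehicle wells' statistic.  Because D is non-negative and directionless, the
reported KS Z is signed by the direction of the well's mean-distance shift
relative to the pooled vehicle: enhancers positive, suppressors negative.
An alternative mode converts the KS p-value through the standard normal
quantile instead.  Hits are compounds with Z above threshold (default 2,
with 3 as the stricter confirmation level) in **both** replicates; no other
multiplicity control is applied.

Calibration facts (computed in the test suite): with a vehicle reference of
n wells the null Z has SD √((n−1)/(n−3)·(1+1/n)) — 1.25 at n=8 but 1.01 at
n=200 — so calibration studies pool a large vehicle set, as real screens do
across plates.  Under the no-effect null the signed KS Z is mean-zero by
symmetry with SD ≈ 1.0, and the two-replicate hit rate is the square of the
single-replicate rate.  Doubling the motile fraction (0.1 → 0.2) with 1,000
particles per well is detected with essentially 100% power at Z > 2.

## Kymograph analysis

The kymograph resamples each frame along the axon centerline (1 column per
pixel of arc length) taking the maximum intensity within ±3 px perpendicular
to the path — robust to the axon wobbling inside the band.  Rows are time
(downward), columns are arc length from the soma (anterograde rightward).

Traces are 2D detections projected to the nearest point of the centerline
(those farther than 4 px discarded) and linked in the 1D arc-length
coordinate with the same gated assignment.  A trace is motile when
|net Δs| ≥ 2 μm; its direction is the sign of net Δs, so anterograde% +
retrograde% = overall motile% exactly.  Reversing the soma marker swaps the
direction labels and changes no magnitude.

**Velocity.**  The reported velocity is run speed: the arc-length trace is
moving-average smoothed (window 5 frames), frames slower than 0.05 μm/s are
treated as pauses, and speed is total smoothed |Δs| over moving frames
divided by the time in them.  Pauses are excluded because the average
velocities quoted for axonal transport track the speed while moving; a
total-time velocity is obtainable by setting the pause threshold to zero.
Smoothing flattens the first and last half-window, a ≈1% end effect.
Constant run speeds of 0.10 and 0.21 μm/s are recovered within ~3% (well
inside 10%) from rendered movies.

**Known failure mode:** when a motile mitochondrion passes within the link
gate of a stationary one, minimum-distance assignment can swap their
identities, occasionally splitting one run into two motile-looking traces
and overcounting percent motile on that axon.  Appearance-based crossing
resolution is out of scope; per-axon percent motile should be averaged over
many axons, as experimental kymograph studies do.

## Pixel-variance score

Frames are binarized (Otsu per frame; absolute threshold available) and the
cell mask is the largest connected component of the union of foregrounds
(one cell per field assumed).  A pixel occupied a fraction q of the frames
has binary population variance exactly q(1−q); the cell score is the mean
over the mask, and scores are reported as fold-of-control.  Population (not
sample) variance preserves the closed form; binarization makes the score
invariant to global intensity gain.  A raw-intensity variance mode is
retained as an option.

The score is zero for a static movie, strictly increasing in network
displacement rate within its dynamic range (0.002–0.018 μm/s at the default
geometry, verified per-seed), and ranks progressive translation above
in-place oscillation of equal path length.  **Limitation:** once segment
excursions repeatedly exceed the tube width, trail pixels equilibrate at
intermediate occupancy and the score saturates — the proxy separates slow
remodelling regimes, not fast ones.  A single variance window over the whole
movie is used; temporal chunking variants exist in practice and would change
absolute (not relative) scores.

## Dose-response

Responses are first converted to percent of maximum activity within the
dataset, y′ = 100·(y − min)/(max − min), then fitted with the variable-slope
four-parameter logistic on log10 concentration,

    y = bottom + (top − bottom) / (1 + 10^((logEC50 − log c)·hill)),

by unweighted least squares.  Initialisation takes top/bottom from the data
extremes and logEC50 from the concentration nearest half-maximal response,
with a multi-start over hill ∈ {+1, −1}; parameters are unconstrained and
reported in the canonical top ≥ bottom orientation.  Standard errors come
from the Gauss–Newton covariance.  Noise-free data in the model class are
recovered to machine precision; at 5% response noise with 4 replicates over
8 log-spaced concentrations the mean relative EC50 error is ~7–11% (the
percent-max renormalisation of noisy extremes is the dominant contributor).
Concentrations spanning under a decade trigger a poorly-identified warning.
Biphasic (bell-shaped) dose-responses are out of scope; fitting one with
this model will under-report the top plateau.

## Reproducibility and problem sizes

A single root seed drives every stage; per-well/per-stage generators are
spawned deterministically from it, and identical configs reproduce
byte-identical tabular outputs (fixed float formatting).  The validation
studies use desk-scale problem sizes chosen to keep Monte-Carlo error well
below each tolerance: 10 field movies per motile-fraction level, 1,000
particles per screening well with 200-well vehicle pools, 16 axon segments
for kymograph baselines (the scale of a real control dataset), 10 seeds per
displacement rate, and 20 dose-response replicates.
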