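# Methods

`pcmotion` quantifies the motion and intensity of discrete nuclear
structures — Polycomb (PC) bodies and condensed chromatin domains — in
time-lapse microscopy of live *Drosophila* embryo nuclei, and ships a
synthetic-data generator that reproduces the statistical structure those
analyses assume.  This note records the models, the defaults and why, the
numerical choices, and what the synthetic validation does and does not
establish about real data.  Units are µm and seconds throughout;
intensities are arbitrary units.

## Motion model

Each tracked body moves as a two-dimensional Ornstein–Uhlenbeck (OU)
process around an anchor: Brownian motion with a linear restoring force,
the standard model for tethered, confined particles.  We simulate the
exact AR(1) discretisation

    x[k+1] = a x[k] + σ √(1 − a²) ε,    a = exp(−Δt/τ),

started from the stationary distribution.  The per-axis stationary
standard deviation is σ = R_c/2, so the long-lag MSD plateau is
4σ² = R_c² and the confinement-radius estimator `sqrt(plateau)` targets
R_c directly.  OU was chosen over reflected Brownian motion in a disc
because it is analytically tractable (the plateau is exact) and matches
the observed behaviour of confined tracks, which wander off and then
return near their point of origin.

On top of the individual wobble:

* **Coordinated long-range drift.**  Anchors belong to groups
  ("higher-order structures", of the order of chromosome-arm
  territories).  Events arrive per group as a Poisson process; during an
  event every anchor of the group translates at constant speed in one
  shared random direction.  This piecewise-constant-velocity model
  matches the directional displacements of up to 1 µm in 10 s seen for
  groups of bodies.
* **Whole-nucleus drift** at constant speed in a random direction,
  removed downstream by nucleus-centred coordinates.
* **Localisation noise**, i.i.d. Gaussian per frame and axis.
* **Intensity–mobility coupling.**  Body intensities are log-normal;
  each body's R_c is scaled by `(I/median)^(−γ)`, renormalised so the
  *ensemble* mean-square R_c is unchanged.  The renormalisation keeps
  the preset radius the recoverable ground truth while still making
  bright bodies measurably slower than faint ones.
* **Fixed-embryo control**: all motion zeroed, noise retained.  Its MSD
  is flat at 4·noise_sd² — the measurement floor.

### Defaults and their provenance

| parameter | default | reason |
|---|---|---|
| R_c (PC body) | 0.29 / 0.20 / 0.14 µm | measured confinement radii at stages 5/11/15 |
| R_c (chromatin) | 0.18 / 0.16 / 0.09 µm | same, for H2Av-GFP domains |
| nucleus area | 23 / 16 / 14 µm² | measured nuclear surfaces at stages 5/11/15 |
| frame interval, length | 0.25 s × 61 frames (15 s) | the short time-lapse schedule |
| pixel size | 70 nm (PC) / 48 nm (chromatin) | acquisition pixel sizes |
| relaxation time τ | 1.0 s | confined MSD/t flattens by ≈ 5 s ≈ 3τ + plateau window |
| event speed, duration | 0.1 µm/s, 10 s | "up to 1 µm in 10 s"; events span 10–30 s |
| event rate | 0.0277 /group/s | about half of 15 s tracks then see an event |
| groups per nucleus | 6 | of the order of major chromosome arms |
| bodies per nucleus | 10 | a few discrete foci per nucleus |
| localisation noise | 15 nm (PC) / 12 nm (chromatin) | fixed-control floor, slightly better for chromatin |
| intensity log-sd, γ | 0.6, 0.4 | few bright + many faint bodies; bright ones clearly slower |
| temperature factor | 0.7 at 18 °C | motion slows when cold; no number is reported, 0.7 is our choice |

Where a row cites a measured value the simulator treats it as the study
condition; the remaining rows are this package's own calibration of
quantities the source observations constrain only qualitatively, fixed
once and used everywhere.

## Trajectory statistics

* **MSD** — time-averaged over all overlapping same-track pairs at each
  lag, then unweighted ensemble mean over tracks.  Computed on
  nucleus-centred ("relative") coordinates so whole-nucleus drift
  cancels.  Overlapping-pair averaging maximises counts at short lags;
  the per-track then unweighted-mean convention weights every object
  equally regardless of track length.
* **MSC** — for a pair of objects, the mean squared change of their
  scalar distance over a lag, on *absolute* coordinates: a common
  translation of both objects cancels in the distance, so MSC needs no
  drift correction and is the statistic of choice when the nucleus
  cannot be segmented.
* **MSD/t** — flat for free diffusion, decaying as 1/t for confined
  motion, increasing for directed motion.
* **Turning (vertex) angles** — the angle at the middle of three
  consecutive positions spaced by one lag, with 180° a straight
  continuation and 0° a full reversal; uniform on [0°, 180°] for an
  isotropic random walk.  This convention is used because confined
  (anti-persistent) motion concentrates mass at *narrow* angles
  (0–60°): at lags well beyond τ, consecutive OU displacements have
  correlation −1/2.  Default bins are six 30° bins; zero-length
  displacements are skipped and counted.
* **Confinement radius** — `sqrt(mean MSD over a plateau window)`;
  default window 3–10 s for 15 s acquisitions, 60–120 s for long ones.
  Whether a "radius of confinement" should instead come from a confined-
  diffusion model fit is a genuinely open convention; `sqrt(plateau)` is
  the documented choice here and is exact for the OU model.
* **Territory radius** — a chromosome-arm territory is approximated as a
  disc of area `nucleus_area / n_arms` (10 arms; the small 4th
  chromosome is not counted), giving 0.86/0.71/0.67 µm at the three
  stages.  Reported rounded to 10 nm.
* **Tests** — MSD/MSC distributions across objects are log-normal, so
  group comparisons use Welch's t-test on natural logs and correlations
  are Pearson on logs.  The two-sample KS test computes
  D = max|ECDF_A − ECDF_B| with the asymptotic Kolmogorov p-value
  (survival function at `sqrt(n_a n_b/(n_a+n_b))·D`); an exact
  permutation p-value is used below a combined n of 100 and available on
  request at any size.

## Two-regime decomposition

Per track we form x = MSD/t at 3 s and y = x − MSD/t at 10 s (lags
resolved to the nearest available lag within half a frame interval).  A
fully plateaued MSD gives y/x = (P/3 − P/10)/(P/3) = 0.7 exactly; a
long-range component holds MSD/t up at 10 s and drives y/x toward or
below 0.  Tracks with y/x ≥ 0.4 are called constrained (ties constrained;
x ≤ 0 abstains).  The 0.4 default was calibrated on labelled simulations:
it balances the two error rates (≈ 3 % constrained, ≈ 8 % long-range,
94 % overall on a mixture of clean examples), whereas the geometric
midpoint 0.5 under-serves the constrained class.  The threshold is a
reconstruction — the original analysis separated the regimes by eye on
the same scatter — and stays configurable.

Per pair, rho = mean MSC/t over 3–10 s divided by the mean of the two
tracks' own mean MSD/t.  Shared drift inflates MSD but barely changes
the pair distance (rho → 0); independently moving pairs — confined or
drifting apart — sit near or above 1 (for two far-separated confined
objects the distance change projects both motions on the separation
axis and rho ≈ 1 exactly).  Calls: coordinated ≤ 0.2, independent ≥ 1.0,
otherwise *ambiguous* (an explicit abstention).  The band was calibrated
on labelled simulated pairs; accuracy is therefore reported over decided
calls together with the abstention rate (≈ 40 % under the default
conditions).  Two limits are intrinsic, not implementation artifacts: a
drift perpendicular to the pair separation leaves the scalar distance
unchanged, and two groups that coincidentally drift in near-parallel
directions are indistinguishable from one coordinated structure by any
distance-change statistic.  The labelled validation therefore defines
independent-drift pairs as pairs from different groups whose net drift
directions differ by at least 60°.

The intensity-stratified comparison takes nuclei with exactly two
tracked objects, assigns the brighter to the "intense" group (ties to
the lower object id), and compares MSD/t at 1 s with the log t-test.

## Image pipeline

Detection replaces the commercial segmentation of the original
workflow: 3×3 median filter (reflected edges), Gaussian smoothing, local
maxima above threshold with non-maximum suppression, sub-pixel
refinement by background-subtracted intensity-weighted centroid (the
local background is the window-border median, so a constant offset does
not pull the centroid to the window centre).  Linking is greedy mutual
nearest neighbour under a displacement cap, no gap closing — the tracked
bodies are bright and persistent — with ties broken toward the smaller
track id for determinism.  Nucleus traces are intensity-weighted
centroids above an Otsu (overridable) threshold.  Pixel (0, 0) is
centred at the origin; µm = pixel index × pixel size.  The detector is a
stand-in validated on synthetic stacks only (sub-0.1 px at high SNR,
≥ 99 % link identity at 4× spacing-to-step ratio); the original
segmentation rules are not public.

## Enrichment

`body_max` mode: maximum protein intensity in a body mask over the mean
in the nucleus mask.  `fish_mean` mode: mean protein intensity inside a
FISH spot's half-maximum connected region over the nuclear mean; the
half-max rule is deterministic and scale-free where the original
commercial "FISH volume" segmentation is unspecified, and the fraction
is exposed.  Spot counting (1 = paired homologues, 2 = unpaired) uses
local maxima above half the brightest in-nucleus FISH pixel.  Line
profiles sample 21 points over 1 µm (≈ 48 nm spacing, the I-FISH pixel
size) through the FISH maximum by bilinear interpolation, normalised to
the mean of the two end points; default orientation is the image x axis
(the original orientation is unstated), with a four-orientation average
available.  All ratios are invariant to any positive gain on the protein
channel.  Analysis is 2D; 3D inputs should be reduced to optical
sections by the caller.

## FLIP kinetics

Two well-mixed compartments exchange fluorescent protein: body B and
nucleoplasm N with dB/dt = k_bind·N − k_release·B.  Between scheduled
events the ODE is stepped exactly (exponential relaxation to the
exchange equilibrium); each bleach pulse multiplies the spot-resident
fluorescent fraction by (1 − efficiency), apportioned between the
compartments by `spot_overlap_body`.  Pulses fire at integer multiples
of the bleach interval, strictly after any frame recorded at the same
instant, so the first frame is always pre-bleach.  The default schedule
is a frame every 1.3 s for 80 s with a pulse every two frames and a
~500 nm spot.  A stochastic mode propagates discrete fluorophores
through the same Markov dynamics (exact two-state transition
probabilities, binomial bleaching).

Extraction reads, per frame, the body maximum inside the nucleus
excluding the bleach spot, and the nucleoplasm mean excluding both the
spot and a 0.25 µm disc around the first-frame body maximum (the spot
radius, so bleached pixels never contaminate either readout).  Traces
are normalised to their first frame — whether the original curves were
normalised to the first frame or to an unbleached reference nucleus is
unstated; first-frame normalisation is the documented default.  Curves
are compared pointwise after linear interpolation onto a common grid,
summarised by the time to 50 % loss (right-censored at the last time
point if never reached).  Rates are deliberately *not* fitted: the
readout of interest is the curve, and a single-exponential fit would
mis-state the two-compartment kinetics.

## Validation battery and problem sizes

`pcmotion.validation` regenerates every check from a seed;
`scripts/acceptance.py` writes the results as JSON.  Sizes were chosen
so the battery completes in well under a minute on one core: 500
Brownian tracks for the 4DΔ closed form (< 5 % at the first five lags);
20 replicates × 200 event-free stage-11 tracks per marker for
confinement-radius recovery (median error 1–2 %); 100 replicates × 10⁴
angles for the uniformity null and the confined anti-persistence check;
100 + 100 labelled tracks and 50 + 50 labelled pairs for the regime and
pair classifiers; 200 FISH scenes at 1 % noise for the enrichment round
trip (r > 0.999) plus 200 uniform-protein null scenes; 2000 null
replicates for the log t-test type-I rate and a brute-force-ECDF /
permutation cross-check of the KS test.

What passing shows — and does not.  The generator reproduces the
*statistical structure* the analyses assume: OU confinement with a known
plateau, shared piecewise drift, log-normal intensities,
intensity–mobility coupling, Gaussian localisation noise, two-compartment
bleaching, Gaussian-spot scenes.  Real recordings add photobleaching of
the tracked signal, anisotropic and depth-dependent PSFs, segmentation
errors on touching bodies, mitotic and moving nuclei, and motion models
richer than OU (anomalous subdiffusion in particular).  Parameter
recovery and classification accuracies reported here are therefore upper
bounds for ideal-model data, not guarantees for microscope output; the
in-vivo headline numbers (the stage-wise radii, the 560 nm long-lag
plateau, the ~90 % homeotic colocalization) enter as simulator presets
and qualitative expectations, not as desk-reproducible results.

## Known limitations

* Whole-track classification only; no changepoint or HMM segmentation of
  mixed tracks, so a track that drifts briefly near the edge of its
  15 s window is genuinely ambiguous (such grazing events are excluded
  from the labelled validation classes).
* The pair statistic is distance-based and blind to parallel independent
  drift and to drift perpendicular to the separation (see above).
* No 3D analysis: z is discarded on input (coarse z-sampling makes axial
  displacements unreliable), enrichment is per optical section.
* No FRAP/reaction–diffusion modelling of the bleach spot; the
  two-compartment model ignores diffusion gradients inside the
  nucleoplasm.
* The linker has no gap closing; a detection dropout terminates a track.
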