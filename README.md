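# pcmotion

Quantitative motion and intensity analysis of discrete nuclear
structures — Polycomb (PC) bodies and condensed chromatin domains — in
time-lapse microscopy of live *Drosophila* embryo nuclei.

Interphase chromatin is not a well-mixed polymer solution: nuclear
bodies wander off and return near their point of origin, groups of them
occasionally glide together over micron distances, and both behaviours
slow down as the embryo develops.  `pcmotion` provides the statistics
needed to quantify this from particle tracks and images, and a
synthetic-data generator with full ground truth for validating every
estimator.  It is aimed at people analysing single-particle-tracking or
nuclear-body time-lapse data who need drift-robust motion statistics and
an honest decomposition into confined and directed components.

## What it computes

* **MSD** — mean square displacement of one object over a time lag, in
  nucleus-centred coordinates (time-averaged, overlapping pairs):
  `MSD(Δ) = ⟨|r(t+Δ) − r(t)|²⟩_t`.
* **MSC** — mean square change of the scalar distance d(t) between two
  objects, `MSC(Δ) = ⟨(d(t+Δ) − d(t))²⟩_t`, computed on uncorrected
  coordinates: nuclear drift cancels in a distance by construction.
* **MSD/t diagnostics** — flat for free diffusion (4D), decaying as 1/t
  for confined motion, increasing for directed motion.
* **Turning (vertex) angles** — uniform on [0°, 180°] for a planar
  random walk; confined motion over-represents narrow angles (0–60°).
* **Confinement radius** `R_c = sqrt(MSD plateau)` and chromosome-arm
  **territory radius** `sqrt(area/(n_arms·π))`.
* **Two-regime decomposition** — per track, the scatter of MSD/t at 3 s
  against its drop from 3 s to 10 s separates constrained from
  long-range motion (a pure plateau gives the ratio 0.7 exactly); per
  pair, the ratio rho = MSC/t ÷ MSD/t separates coordinated
  (shared-drift) from independently moving pairs, with an explicit
  abstention band.
* **Intensity analyses** — max-in-body and mean-in-FISH-volume
  enrichment ratios, cumulative histograms, 1 µm line profiles, paired
  vs unpaired locus comparison (KS test).
* **FLIP kinetics** — two-compartment bleaching model
  `dB/dt = k_bind·N − k_release·B` with periodic pulses, curve
  extraction from image series, and time-to-50 %-loss comparison.
* **Synthetic data** — Ornstein–Uhlenbeck wobble around anchors
  (plateau R_c² by construction), Poisson group-drift events, nucleus
  drift, log-normal intensities anticorrelated with mobility,
  localisation noise, fixed-embryo controls, rendered image stacks,
  two-channel FISH scenes and FLIP series — all with ground-truth
  labels.

Stage presets (developmental stages 5/11/15, PC bodies and chromatin
domains, 25 °C and 18 °C variants) encode the measured nuclear areas,
confinement radii and acquisition schedules; see `pcmotion.presets`.

## Worked example

```python
import pcmotion as pm

preset = pm.get_preset("pc_stage11")
sim = pm.simulate_tracks(preset, n_nuclei=20, seed=0)
rel = pm.to_relative(sim.trackset, sim.nucleus_traces)

curves = [pm.compute_msd(t) for t in rel]
points, _ = pm.regime_scatter(curves)
labels = pm.classify_regime(points)
constrained_ids = {l.object_id for l in labels if l.label == "constrained"}
print(f"tracks: {len(curves)}, constrained: {len(constrained_ids)}")

ensemble = pm.ensemble_curve([c for c in curves
                              if c.object_id in constrained_ids])
radius = pm.confinement_radius(ensemble, window_s=(3, 10))
print(f"constrained-track MSD plateau (3-10 s): {radius.plateau_um2:.4f} um^2")
print(f"confinement radius: {1000 * radius.radius_um:.0f} nm "
      f"(preset ground truth {1000 * preset.confinement_radius_um:.0f} nm)")

hist = pm.turning_angle_histogram(rel, lag_s=0.5)
print(f"fraction of narrow (0-60 deg) turning angles: "
      f"{hist.frequency[:2].sum():.2f}  (random walk: 0.33)")

print(f"arm territory radius at stage 11: "
      f"{pm.territory_radius(preset.nucleus_area_um2, 10):.2f} um")
```

prints

```
tracks: 200, constrained: 124
constrained-track MSD plateau (3-10 s): 0.0496 um^2
confinement radius: 223 nm (preset ground truth 200 nm)
fraction of narrow (0-60 deg) turning angles: 0.41  (random walk: 0.33)
arm territory radius at stage 11: 0.71 um
```

About half of the simulated tracks experience a long-range drift event,
so the regime classifier keeps 124/200 as constrained-only; their pooled
MSD plateau recovers the preset confinement radius (the +11 % here is
one 20-nucleus draw — the validation battery below measures 1–2 % median
error over replicates).  Narrow angles at 41 % against the 33 %
random-walk expectation are the anti-persistence signature of tethered
motion, and the constrained radius sits well below the 0.71 µm arm
territory: individual bodies explore only a small fraction of their
chromosome's territory unless a coordinated drift moves the whole
neighbourhood.

A CLI mirrors the library (`pcmotion simulate tracks|images|fish|flip`,
`pcmotion detect`, `pcmotion link`, `pcmotion motion msd|msc|angles|radius`,
`pcmotion regimes classify|pairs|intensity`,
`pcmotion enrich fish|profile|compare`, `pcmotion flip compare`); all
tables are tab-delimited text.

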