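"""End-to-end validation runs on synthetic data with known ground truth.

Each function regenerates its inputs from a seed, runs the relevant part
of the analysis pipeline, and returns summary metrics.  These runs back
both the acceptance test suite and ``scripts/acceptance.py``; problem
sizes are chosen so the whole battery completes in a few minutes on one
core (the methods note documents the sizes).
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats

from .enrichment import fish_enrichment
from .flip import (FlipSimConfig, compare_flip_conditions, extract_flip_curves,
                   render_flip_stack, simulate_flip_series)
from .motion import (compute_msc, compute_msd, confinement_radius,
                     ensemble_curve, log_t_test, territory_radius,
                     turning_angle_histogram, two_sample_ks)
from .presets import STAGE_PRESETS
from .regimes import classify_pair, classify_regime, regime_scatter
from .synthetic import (FishSceneConfig, simulate_brownian_tracks,
                        simulate_fish_scene, simulate_tracks)
from .tracking import to_relative

#: cumulative drift-event overlap (s) above which a track counts as a
#: clean "with-drift-event" example (the event crosses the 3-10 s
#: analysis window); shorter grazing events are not a clean class
EVENT_OVERLAP_MIN_S = 5.0

#: minimum angle between two groups' net drift directions for a pair to
#: count as a clean "independent-drift" example: near-parallel drifts are
#: geometrically indistinguishable from coordination for any
#: distance-change statistic
INDEPENDENT_ANGLE_MIN_DEG = 60.0


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


# ------------------------------------------------------------------ radii

def territory_radii() -> dict[str, float]:
    """Chromosome-arm territory radii from the stage nuclear areas."""
    return {
        "stage5": territory_radius(STAGE_PRESETS["pc_stage5"].nucleus_area_um2, 10),
        "stage11": territory_radius(STAGE_PRESETS["pc_stage11"].nucleus_area_um2, 10),
        "stage15": territory_radius(STAGE_PRESETS["pc_stage15"].nucleus_area_um2, 10),
    }


# -------------------------------------------------------------- Brownian

def brownian_msd_error(seed: int, n_tracks: int = 500,
                       diffusion: float = 0.01) -> dict[str, float]:
    """Worst relative deviation of ensemble MSD from 4*D*t (first 5 lags)."""
    ts = simulate_brownian_tracks(n_tracks, 61, 0.25, diffusion, seed=seed)
    ens = ensemble_curve([compute_msd(t) for t in ts.tracks])
    rel = np.abs(ens.msd_um2[:5] / (4 * diffusion * ens.lag_s[:5]) - 1.0)
    return {"max_rel_err": float(rel.max()), "n": n_tracks}


# ---------------------------------------------------- confinement radius

def confinement_recovery(seed: int, preset_name: str, n_tracks: int = 200,
                         n_replicates: int = 20) -> dict[str, float]:
    """Median recovered confinement radius over replicate simulations.

    Tracks are event-free OU trajectories from the preset (localisation
    noise and nucleus drift on); the estimator runs the full pipeline:
    nucleus-centred coordinates, per-track MSD, ensemble mean, plateau
    window 3-10 s.
    """
    preset = STAGE_PRESETS[preset_name].replace(event_rate_per_s=0.0)
    n_nuclei = math.ceil(n_tracks / preset.n_bodies_per_nucleus)
    radii = []
    for rep_seed in _child_seeds(seed, n_replicates):
        sim = simulate_tracks(preset, n_nuclei, seed=rep_seed)
        rel = to_relative(sim.trackset, sim.nucleus_traces)[:n_tracks]
        window_lags = np.arange(12, 41) * preset.frame_interval_s
        ens = ensemble_curve([compute_msd(t, lags_s=window_lags) for t in rel])
        radii.append(confinement_radius(ens, window_s=(3.0, 10.0)).radius_um)
    median = float(np.median(radii))
    return {"median_radius_um": median,
            "true_radius_um": preset.confinement_radius_um,
            "rel_err": abs(median / preset.confinement_radius_um - 1.0),
            "n": n_tracks * n_replicates}


# ------------------------------------------------------- turning angles

def angle_calibration(seed: int, n_replicates: int = 100) -> dict[str, float]:
    """Uniformity of Brownian angles; anti-persistence of confined ones.

    Per replicate: 10^4 Brownian vertex angles are tested for uniformity
    over six 30-degree bins (chi-square at alpha = 0.01), and confined OU
    tracks are checked for a 0-60 degree frequency above 1/3 at a lag of
    three relaxation times.
    """
    ou_preset = STAGE_PRESETS["pc_stage11"].replace(
        event_rate_per_s=0.0, nucleus_drift_speed_um_s=0.0)
    lag_ou = 3.0 * ou_preset.relaxation_time_s
    brown_pass = narrow_pass = 0
    for rep_seed in _child_seeds(seed, n_replicates):
        ts = simulate_brownian_tracks(180, 61, 0.25, 0.01, seed=rep_seed)
        hist = turning_angle_histogram(ts.tracks, 0.25)
        counts = hist.frequency * hist.n_angles
        expected = hist.n_angles / 6.0
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        brown_pass += stats.chi2.sf(chi2, df=5) > 0.01

        sim = simulate_tracks(ou_preset, 10, seed=rep_seed + 1)
        ou_hist = turning_angle_histogram(sim.tracks, lag_ou)
        narrow_pass += ou_hist.frequency[:2].sum() > 1.0 / 3.0
    return {"uniform_pass_rate": brown_pass / n_replicates,
            "narrow_angle_pass_rate": narrow_pass / n_replicates,
            "n": n_replicates}


# ------------------------------------------------------ regime and pairs

def _drift_overlap(truth) -> float:
    return sum(e.duration_s for e in truth.events)


def _net_drift(truth) -> np.ndarray:
    return sum((np.asarray(e.velocity_um_s) * e.duration_s for e in truth.events),
               np.zeros(2))


def regime_accuracy(seed: int, n_per_class: int = 100) -> dict[str, float]:
    """Constrained vs long-range accuracy on a labelled stage-11 mixture.

    Constrained-only tracks have no drift event; with-event tracks have a
    drift crossing the analysis window (cumulative overlap >= 5 s).
    """
    preset = STAGE_PRESETS["pc_stage11"]
    ratios = {"constrained": [], "long_range": []}
    for sim_seed in _child_seeds(seed, 200):
        sim = simulate_tracks(preset, 10, seed=sim_seed)
        rel = to_relative(sim.trackset, sim.nucleus_traces)
        curves = [compute_msd(t) for t in rel]
        points, _ = regime_scatter(curves)
        for pt in points:
            truth = sim.truth[pt.object_id]
            overlap = _drift_overlap(truth)
            if truth.constrained_only and len(ratios["constrained"]) < n_per_class:
                ratios["constrained"].append(pt)
            elif overlap >= EVENT_OVERLAP_MIN_S and \
                    len(ratios["long_range"]) < n_per_class:
                ratios["long_range"].append(pt)
        if all(len(v) >= n_per_class for v in ratios.values()):
            break
    correct = 0
    for want, points in ratios.items():
        labels = classify_regime(points)
        correct += sum(lab.label == want for lab in labels)
    n = sum(len(v) for v in ratios.values())
    return {"accuracy": correct / n, "n": n}


def pair_accuracy(seed: int, n_per_class: int = 50) -> dict[str, float]:
    """Coordinated vs independent pair calls on labelled simulated pairs.

    Same-group pairs share a drift event (>= 5 s overlap); independent
    pairs come from different groups, each drifting >= 5 s, with net
    drift directions at least 60 degrees apart.  Accuracy is scored over
    decided (non-ambiguous) calls; the abstention rate is reported.
    """
    preset = STAGE_PRESETS["pc_stage11"]
    labels = {"coordinated": [], "independent": []}
    for sim_seed in _child_seeds(seed + 1, 400):
        sim = simulate_tracks(preset, 10, seed=sim_seed)
        rel = {t.object_id: t for t in
               to_relative(sim.trackset, sim.nucleus_traces)}
        curves = {}
        for nid, members in sim.trackset.by_nucleus().items():
            drifted = [t for t in members
                       if _drift_overlap(sim.truth[t.object_id])
                       >= EVENT_OVERLAP_MIN_S]
            for a, b in combinations(drifted, 2):
                ta, tb = sim.truth[a.object_id], sim.truth[b.object_id]
                if ta.group_id == tb.group_id:
                    want = "coordinated"
                else:
                    va, vb = _net_drift(ta), _net_drift(tb)
                    cosang = (va @ vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
                    if math.degrees(math.acos(np.clip(cosang, -1, 1))) \
                            < INDEPENDENT_ANGLE_MIN_DEG:
                        continue
                    want = "independent"
                if len(labels[want]) >= n_per_class:
                    continue
                for tr in (a, b):
                    if tr.object_id not in curves:
                        curves[tr.object_id] = compute_msd(rel[tr.object_id])
                res = classify_pair(curves[a.object_id], curves[b.object_id],
                                    compute_msc(a, b))
                labels[want].append(res.label)
        if all(len(v) >= n_per_class for v in labels.values()):
            break
    decided = correct = ambiguous = 0
    for want, got in labels.items():
        for label in got:
            if label == "ambiguous":
                ambiguous += 1
            else:
                decided += 1
                correct += label == want
    n = sum(len(v) for v in labels.values())
    return {"decided_accuracy": correct / decided if decided else float("nan"),
            "ambiguous_rate": ambiguous / n, "n": n, "n_decided": decided}


# --------------------------------------------------------- fixed control

def fixed_control_floor(seed: int, n_nuclei: int = 20) -> dict[str, float]:
    """Fixed-embryo control: flat MSD at the localisation-noise floor.

    The ensemble MSD of motion-free tracks must equal 4 * noise_sd^2 at
    every lag, and the flat curve sits exactly on the constrained-regime
    plateau anchor y/x = 0.7.
    """
    preset = STAGE_PRESETS["pc_stage11"]
    sim = simulate_tracks(preset, n_nuclei, fixed_control=True, seed=seed)
    ens = ensemble_curve([compute_msd(t) for t in sim.tracks])
    floor = 4.0 * preset.localization_noise_sd_um ** 2
    points, _ = regime_scatter([ens])
    label = classify_regime(points)[0].label
    return {"msd_over_floor": float(ens.msd_um2.mean() / floor),
            "max_lag_deviation": float(np.abs(ens.msd_um2 / floor - 1.0).max()),
            "ratio_y_over_x": points[0].ratio,
            "classified_constrained": float(label == "constrained"),
            "n": len(sim.tracks)}


# ----------------------------------------------------------------- FLIP

def flip_validation(seed: int) -> dict[str, float]:
    """FLIP round trip and temperature monotonicity.

    Renders a deterministic image series from the two-compartment model,
    re-extracts both loss curves, and compares a 0.7x-rate (18 C)
    simulation with the reference (25 C) body trace.
    """
    cfg = FlipSimConfig()
    st = render_flip_stack(cfg)
    body, nucleo = extract_flip_curves(
        st.stack, st.nucleus_mask, st.body_trace.t_s,
        pixel_size_um=st.pixel_size_um, spot_center_px=st.spot_center_px)
    err = max(float(np.abs(body.values - st.body_trace.values).max()),
              float(np.abs(nucleo.values - st.nucleo_trace.values).max()))
    warm, _ = simulate_flip_series(cfg)
    cold, _ = simulate_flip_series(FlipSimConfig(
        k_bind_per_s=0.7 * cfg.k_bind_per_s,
        k_release_per_s=0.7 * cfg.k_release_per_s))
    res = compare_flip_conditions(cold, warm)
    return {"roundtrip_max_abs_err": err,
            "t50_cold_s": res.t50_a_s, "t50_warm_s": res.t50_b_s,
            "t50_ratio_cold_over_warm": res.t50_a_s / res.t50_b_s,
            "n": int(st.body_trace.t_s.size)}


# ----------------------------------------------------------- enrichment

def enrichment_roundtrip(seed: int, n_scenes: int = 200) -> dict[str, float]:
    """Measured vs truth FISH enrichment over synthetic scenes at 1% noise."""
    seeds = _child_seeds(seed + 2, n_scenes)
    truths, measured = [], []
    for s in seeds:
        scene = simulate_fish_scene(FishSceneConfig(
            noise_sd=0.1, fish_in_body_probability=0.7, seed=s))
        rec = fish_enrichment(scene.pc_image, scene.fish_image,
                              scene.nucleus_mask)
        truths.append(scene.truth_ratios[0])
        measured.append(rec[0].ratio)
    truths_arr, measured_arr = np.asarray(truths), np.asarray(measured)
    rel_err = np.abs(measured_arr / truths_arr - 1.0)
    null = []
    for s in _child_seeds(seed + 3, n_scenes):
        scene = simulate_fish_scene(FishSceneConfig(
            body_amplitudes=(), fish_in_body_probability=0.0,
            noise_sd=0.1, seed=s))
        null.append(fish_enrichment(scene.pc_image, scene.fish_image,
                                    scene.nucleus_mask)[0].ratio)
    return {"truth_correlation_r": float(np.corrcoef(truths_arr, measured_arr)[0, 1]),
            "median_rel_err": float(np.median(rel_err)),
            "uniform_null_mean_ratio": float(np.mean(null)),
            "n": n_scenes}


# --------------------------------------------------- statistical checks

def stats_calibration(seed: int, n_replicates: int = 2000,
                      n_per_sample: int = 100) -> dict[str, float]:
    """Type-I rate of the log t-test and KS cross-checks.

    Null replicates draw two log-normal samples with a common log-mean;
    the KS statistic is compared with a brute-force ECDF scan and its
    asymptotic p-value with a label-permutation estimate at n = 50 + 50.
    """
    rng = np.random.default_rng(seed + 4)
    rejections = 0
    for _ in range(n_replicates):
        a = rng.lognormal(mean=1.0, sigma=0.8, size=n_per_sample)
        b = rng.lognormal(mean=1.0, sigma=0.8, size=n_per_sample)
        rejections += log_t_test(a, b).pvalue < 0.05
    brute_diff, perm_diffs = 0.0, []
    for _ in range(5):
        a = rng.normal(size=50)
        b = rng.normal(0.25, 1.0, size=50)
        asymp = two_sample_ks(a, b, method="asymp")
        perm = two_sample_ks(a, b, method="permutation",
                             n_permutations=20_000,
                             seed=int(rng.integers(2 ** 31)))
        grid = np.concatenate([a, b])
        d_brute = float(np.max(np.abs(
            np.mean(a[:, None] <= grid[None, :], axis=0)
            - np.mean(b[:, None] <= grid[None, :], axis=0))))
        brute_diff = max(brute_diff, abs(asymp.statistic - d_brute))
        perm_diffs.append(abs(perm.pvalue - asymp.pvalue) / asymp.pvalue)
    return {"t_type1_rate": rejections / n_replicates,
            "ks_bruteforce_abs_diff": brute_diff,
            "ks_perm_vs_asymp_rel_diff": float(np.median(perm_diffs)),
            "n": n_replicates}
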