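"""Synthetic trajectory, image-stack and FISH-scene generators.

The motion model mirrors what the analyses assume about nuclear bodies in
live embryo nuclei:

* each body wobbles around an anchor point as a 2D Ornstein–Uhlenbeck (OU)
  process — Brownian motion with a linear restoring force.  The per-axis
  stationary standard deviation is ``sigma = R_c / 2`` so the long-lag MSD
  plateau equals ``R_c**2`` for a body with confinement radius ``R_c``;
* anchors belong to groups ("higher-order structures").  Each group
  receives occasional long-range drift events (Poisson arrivals) during
  which all of its anchors translate at constant velocity in a shared
  random direction;
* the whole nucleus drifts slowly in a fixed random direction;
* every sample carries independent Gaussian localisation noise;
* body intensities are log-normal, and brighter bodies are assigned
  smaller confinement radii (intensity–mobility anticorrelation).

A fixed-control mode freezes all motion and keeps only the localisation
noise, emulating tracking of chemically fixed embryos.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .flip import FlipSimConfig, simulate_flip_series  # noqa: F401  (re-export)
from .presets import InvalidConfigurationError, StagePreset
from .tracks import Track, TrackSet, NucleusTrace, uniform_times


@dataclass(frozen=True)
class DriftEvent:
    """One long-range drift event, clipped to the acquisition window."""

    start_s: float
    end_s: float
    velocity_um_s: tuple[float, float]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class TrackTruth:
    """Ground-truth labels for one simulated track."""

    anchor_um: np.ndarray
    confinement_radius_um: float     # effective per-body R_c
    group_id: int
    events: list[DriftEvent]
    constrained_only: bool
    intensity: float


@dataclass
class SimulatedTrackSet:
    """Simulated tracks plus ground truth for every recoverable parameter."""

    trackset: TrackSet
    truth: dict[int, TrackTruth]     # keyed by object_id
    preset: StagePreset
    seed: int
    fixed_control: bool = False

    @property
    def tracks(self) -> list[Track]:
        return self.trackset.tracks

    @property
    def nucleus_traces(self) -> dict[int, NucleusTrace]:
        return self.trackset.nucleus_traces

    def subset(self, nucleus_id: int) -> "SimulatedTrackSet":
        tracks = [t for t in self.tracks if t.nucleus_id == nucleus_id]
        if not tracks:
            raise KeyError(f"no nucleus {nucleus_id} in this track set")
        ts = TrackSet(tracks=tracks,
                      nucleus_traces={nucleus_id: self.nucleus_traces[nucleus_id]})
        truth = {t.object_id: self.truth[t.object_id] for t in tracks}
        return SimulatedTrackSet(trackset=ts, truth=truth, preset=self.preset,
                                 seed=self.seed, fixed_control=self.fixed_control)


def _draw_events(rng: np.random.Generator, rate: float, speed: float,
                 duration: float, total: float) -> list[DriftEvent]:
    """Poisson drift events whose intervals intersect [0, total]."""
    if rate <= 0 or speed <= 0 or duration <= 0:
        return []
    window = total + duration
    n = rng.poisson(rate * window)
    events = []
    for _ in range(n):
        start = rng.uniform(-duration, total)
        end = start + duration
        theta = rng.uniform(0.0, 2.0 * math.pi)
        vel = (speed * math.cos(theta), speed * math.sin(theta))
        clip_start, clip_end = max(start, 0.0), min(end, total)
        if clip_end > clip_start:
            events.append(DriftEvent(clip_start, clip_end, vel))
    events.sort(key=lambda e: e.start_s)
    return events


def _event_displacement(events: list[DriftEvent], t: np.ndarray) -> np.ndarray:
    """Cumulative anchor displacement (n_frames, 2) from drift events."""
    disp = np.zeros((t.shape[0], 2))
    for ev in events:
        lam = np.clip(t, ev.start_s, ev.end_s) - ev.start_s
        disp += lam[:, None] * np.asarray(ev.velocity_um_s)
    return disp


def _ou_paths(rng: np.random.Generator, sigma: np.ndarray, tau: float,
              dt: float, n_frames: int) -> np.ndarray:
    """Stationary OU paths, shape (n_bodies, n_frames, 2).

    Exact AR(1) discretisation: x_{k+1} = a x_k + sigma sqrt(1-a^2) eps,
    a = exp(-dt/tau), started from the stationary distribution.
    """
    n_bodies = sigma.shape[0]
    a = math.exp(-dt / tau)
    b = math.sqrt(1.0 - a * a)
    out = np.empty((n_bodies, n_frames, 2))
    s = sigma[:, None]
    out[:, 0, :] = rng.standard_normal((n_bodies, 2)) * s
    noise = rng.standard_normal((n_bodies, n_frames - 1, 2))
    for k in range(1, n_frames):
        out[:, k, :] = a * out[:, k - 1, :] + b * s * noise[:, k - 1, :]
    return out


def simulate_tracks(preset: StagePreset, n_nuclei: int, *,
                    fixed_control: bool = False, seed: int = 0) -> SimulatedTrackSet:
    """Simulate confined + coordinated-drift trajectories for many nuclei.

    Anchors are placed uniformly in a disc of the preset's nuclear radius
    and assigned to ``n_groups_per_nucleus`` groups at random.  See the
    module docstring for the motion model.  With ``fixed_control=True``
    all motion terms are zeroed and only localisation noise remains.

    Returns a :class:`SimulatedTrackSet` whose truth labels record, per
    track, the anchor, effective confinement radius, group id, the drift
    events of its group (clipped to the acquisition window) and whether
    the track is constrained-only (no event overlaps its time span).
    """
    preset.validate()
    if n_nuclei < 1:
        raise InvalidConfigurationError(f"n_nuclei must be >= 1, got {n_nuclei}")
    dt = preset.frame_interval_s
    n_frames = preset.n_frames
    t = uniform_times(n_frames, dt)
    total = preset.duration_s
    temp = preset.temperature_factor

    children = np.random.SeedSequence(seed).spawn(n_nuclei)
    tracks: list[Track] = []
    traces: dict[int, NucleusTrace] = {}
    truth: dict[int, TrackTruth] = {}
    next_object_id = 0

    for nid in range(n_nuclei):
        rng = np.random.default_rng(children[nid])
        nb = preset.n_bodies_per_nucleus
        ng = preset.n_groups_per_nucleus

        # anchors uniform in the nuclear disc
        r = preset.nucleus_radius_um * np.sqrt(rng.uniform(size=nb))
        phi = rng.uniform(0.0, 2.0 * math.pi, size=nb)
        anchors = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        groups = rng.integers(0, ng, size=nb)

        # log-normal intensities; brighter bodies get smaller radii, with
        # the scaling renormalised to keep the ensemble mean-square R_c
        z = rng.standard_normal(nb)
        intensity = np.exp(preset.intensity_log_mean + preset.intensity_log_sd * z)
        gamma = preset.intensity_mobility_exponent
        sig_log = preset.intensity_log_sd
        mobility_scale = np.exp(-gamma * sig_log * z - (gamma * sig_log) ** 2)
        cv = preset.confinement_radius_cv
        if cv > 0:
            s_r = math.sqrt(math.log1p(cv * cv))
            base_rc = preset.confinement_radius_um * np.exp(
                s_r * rng.standard_normal(nb) - 0.5 * s_r * s_r)
        else:
            base_rc = np.full(nb, preset.confinement_radius_um)
        rc = base_rc * mobility_scale

        group_events = {g: _draw_events(
            rng, preset.event_rate_per_s, preset.event_speed_um_s * temp,
            preset.event_duration_s, total) for g in range(ng)}

        drift_dir = rng.uniform(0.0, 2.0 * math.pi)
        drift = preset.nucleus_drift_speed_um_s * np.array(
            [math.cos(drift_dir), math.sin(drift_dir)])
        center = np.outer(t, drift)

        if fixed_control:
            motion = np.zeros((nb, n_frames, 2))
            center = np.zeros_like(center)
            group_events = {g: [] for g in range(ng)}
        else:
            sigma = 0.5 * rc * temp
            motion = _ou_paths(rng, sigma, preset.relaxation_time_s, dt, n_frames)
            for i in range(nb):
                motion[i] += _event_displacement(group_events[groups[i]], t)

        noise = preset.localization_noise_sd_um * rng.standard_normal(
            (nb, n_frames, 2))
        positions = anchors[:, None, :] + motion + center[None, :, :] + noise

        traces[nid] = NucleusTrace(nucleus_id=nid, t_s=t.copy(), center_um=center)
        for i in range(nb):
            oid = next_object_id
            next_object_id += 1
            events = group_events[groups[i]]
            tracks.append(Track(
                object_id=oid, nucleus_id=nid, t_s=t.copy(),
                xy_um=positions[i],
                intensity=np.full(n_frames, intensity[i]),
                group_id=int(groups[i])))
            truth[oid] = TrackTruth(
                anchor_um=anchors[i].copy(),
                confinement_radius_um=float(rc[i]),
                group_id=int(groups[i]),
                events=list(events),
                constrained_only=len(events) == 0,
                intensity=float(intensity[i]))

    ts = TrackSet(tracks=tracks, nucleus_traces=traces)
    return SimulatedTrackSet(trackset=ts, truth=truth, preset=preset, seed=seed,
                             fixed_control=fixed_control)


def simulate_brownian_tracks(n_tracks: int, n_frames: int, frame_interval_s: float,
                             diffusion_um2_s: float, *, seed: int = 0,
                             noise_sd_um: float = 0.0) -> TrackSet:
    """Free 2D Brownian tracks (MSD = 4 D t), a null model for diagnostics."""
    if n_frames < 2 or frame_interval_s <= 0:
        raise InvalidConfigurationError("need n_frames >= 2 and a positive interval")
    rng = np.random.default_rng(seed)
    step_sd = math.sqrt(2.0 * diffusion_um2_s * frame_interval_s)
    steps = rng.standard_normal((n_tracks, n_frames - 1, 2)) * step_sd
    pos = np.concatenate([np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)],
                         axis=1)
    if noise_sd_um > 0:
        pos = pos + noise_sd_um * rng.standard_normal(pos.shape)
    t = uniform_times(n_frames, frame_interval_s)
    tracks = [Track(object_id=i, nucleus_id=0, t_s=t.copy(), xy_um=pos[i])
              for i in range(n_tracks)]
    return TrackSet(tracks=tracks)


# ---------------------------------------------------------------------------
# image-stack rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderedStack:
    """A rendered time-lapse with the ground truth used to make it."""

    stack: np.ndarray                 # (n_frames, H, W) float32
    pixel_size_um: float
    origin_um: np.ndarray             # world position of pixel (0, 0) centre
    positions_px: dict[int, np.ndarray]   # object_id -> (n_frames, 2) as (row, col)

    def world_to_px(self, xy_um: np.ndarray) -> np.ndarray:
        """Map world (x, y) µm to (row, col) pixel coordinates."""
        rel = np.asarray(xy_um) - self.origin_um
        return np.stack([rel[..., 1], rel[..., 0]], axis=-1) / self.pixel_size_um


def _render_gaussians(frame: np.ndarray, centers_px: np.ndarray,
                      amplitudes: np.ndarray, sigma_px: float) -> None:
    """Add isotropic Gaussian spots in place (windowed for speed)."""
    h, w = frame.shape
    half = max(3, int(math.ceil(4.0 * sigma_px)))
    for (row, col), amp in zip(centers_px, amplitudes):
        r0, r1 = int(math.floor(row)) - half, int(math.floor(row)) + half + 1
        c0, c1 = int(math.floor(col)) - half, int(math.floor(col)) + half + 1
        r0c, r1c = max(r0, 0), min(r1, h)
        c0c, c1c = max(c0, 0), min(c1, w)
        if r0c >= r1c or c0c >= c1c:
            continue
        rr = np.arange(r0c, r1c)[:, None] - row
        cc = np.arange(c0c, c1c)[None, :] - col
        frame[r0c:r1c, c0c:c1c] += amp * np.exp(
            -(rr * rr + cc * cc) / (2.0 * sigma_px * sigma_px))


def simulate_image_stack(sim: SimulatedTrackSet, *, psf_sigma_um: float,
                         background: float = 10.0, noise_sd: float = 1.0,
                         seed: int = 0, amplitude_scale: float = 100.0,
                         margin_um: float = 0.7,
                         shape: tuple[int, int] | None = None) -> RenderedStack:
    """Render a single-nucleus track set as a multi-frame grayscale stack.

    Each body is drawn as an isotropic Gaussian of amplitude
    ``amplitude_scale * intensity`` on a constant background, with additive
    Gaussian noise.  The pixel grid convention places the centre of pixel
    (0, 0) at ``origin_um``; positions in µm map to pixels by division by
    the preset pixel size.
    """
    nuclei = {t.nucleus_id for t in sim.tracks}
    if len(nuclei) > 1:
        raise ValueError("simulate_image_stack renders one nucleus at a time; "
                         "use SimulatedTrackSet.subset(nucleus_id) first")
    px = sim.preset.pixel_size_um
    if not sim.tracks:
        if shape is None:
            side = int(math.ceil(2 * (sim.preset.nucleus_radius_um + margin_um) / px))
            shape = (side, side)
        rng = np.random.default_rng(seed)
        stack = np.full((sim.preset.n_frames, *shape), float(background))
        if noise_sd > 0:
            stack += noise_sd * rng.standard_normal(stack.shape)
        return RenderedStack(stack=stack.astype(np.float32), pixel_size_um=px,
                             origin_um=np.zeros(2), positions_px={})
    all_pos = np.concatenate([t.xy_um[:, :2] for t in sim.tracks], axis=0)
    origin = all_pos.min(axis=0) - margin_um
    extent = all_pos.max(axis=0) + margin_um - origin
    if shape is None:
        shape = (int(math.ceil(extent[1] / px)) + 1,
                 int(math.ceil(extent[0] / px)) + 1)
    h, w = shape
    for tr in sim.tracks:
        rel = tr.xy_um[:, :2] - origin
        cols, rows = rel[:, 0] / px, rel[:, 1] / px
        if rows.min() < 0 or cols.min() < 0 or rows.max() > h - 1 or cols.max() > w - 1:
            raise ValueError(f"object {tr.object_id} leaves the image bounds")

    rng = np.random.default_rng(seed)
    n_frames = sim.tracks[0].n_frames
    stack = np.full((n_frames, h, w), float(background), dtype=float)
    positions_px: dict[int, np.ndarray] = {}
    sigma_px = psf_sigma_um / px
    for tr in sim.tracks:
        rel = tr.xy_um[:, :2] - origin
        positions_px[tr.object_id] = np.stack(
            [rel[:, 1] / px, rel[:, 0] / px], axis=-1)
    for k in range(n_frames):
        centers = np.array([positions_px[tr.object_id][k] for tr in sim.tracks])
        amps = np.array([amplitude_scale * (tr.intensity[k] if tr.intensity is not None
                                            else 1.0) for tr in sim.tracks])
        _render_gaussians(stack[k], centers, amps, sigma_px)
    if noise_sd > 0:
        stack += noise_sd * rng.standard_normal(stack.shape)
    return RenderedStack(stack=stack.astype(np.float32), pixel_size_um=px,
                         origin_um=origin, positions_px=positions_px)


# ---------------------------------------------------------------------------
# two-channel FISH scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FishSceneConfig:
    """Configuration of a synthetic two-channel immuno-FISH scene.

    Channel 1 is a nuclear protein signal (uniform background inside the
    nucleus plus Gaussian bodies); channel 2 contains one or two point-like
    FISH spots.  With probability ``fish_in_body_probability`` a spot is
    centred inside one of the bodies, otherwise it is placed uniformly in
    the nucleus interior.
    """

    image_shape: tuple[int, int] = (96, 96)
    pixel_size_um: float = 0.048
    nucleus_radius_um: float = 2.0
    background: float = 10.0
    body_amplitudes: tuple[float, ...] = (30.0, 15.0)
    psf_sigma_um: float = 0.10
    fish_in_body_probability: float = 1.0
    fish_amplitude: float = 50.0
    n_fish_spots: int = 1
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.psf_sigma_um < self.pixel_size_um / 2:
            raise InvalidConfigurationError(
                "psf_sigma_um must be at least half a pixel")
        if any(a < 0 for a in self.body_amplitudes):
            raise InvalidConfigurationError("body amplitudes must be nonnegative")
        if not 0.0 <= self.fish_in_body_probability <= 1.0:
            raise InvalidConfigurationError("fish_in_body_probability must be in [0, 1]")
        if self.n_fish_spots < 1:
            raise InvalidConfigurationError("n_fish_spots must be >= 1")
        h, w = self.image_shape
        half_extent = min(h, w) / 2 * self.pixel_size_um
        if self.nucleus_radius_um + 2 * self.psf_sigma_um >= half_extent:
            raise InvalidConfigurationError("nucleus does not fit inside the image")


@dataclass
class FishScene:
    """A rendered FISH scene with its noiseless truth."""

    pc_image: np.ndarray
    fish_image: np.ndarray
    clean_pc: np.ndarray
    clean_fish: np.ndarray
    nucleus_mask: np.ndarray
    body_masks: list[np.ndarray]
    body_centers_px: np.ndarray        # (n_bodies, 2) as (row, col)
    fish_centers_px: np.ndarray        # (n_spots, 2) as (row, col)
    fish_in_body: list[bool]
    truth_ratios: list[float]          # noiseless mean-in-mask / mean-in-nucleus
    config: FishSceneConfig


def simulate_fish_scene(config: FishSceneConfig) -> FishScene:
    """Render a two-channel FISH/protein scene with known enrichment.

    The truth ratio of each FISH spot is the exact mean of the noiseless
    protein channel inside the spot's half-maximum region divided by its
    mean inside the nucleus mask.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    px = config.pixel_size_um
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rows = np.arange(h)[:, None] - center[0]
    cols = np.arange(w)[None, :] - center[1]
    dist_um = np.sqrt(rows * rows + cols * cols) * px
    nucleus_mask = dist_um <= config.nucleus_radius_um

    sigma_px = config.psf_sigma_um / px
    inner = 0.7 * config.nucleus_radius_um / px   # keep structures off the rim

    def random_interior() -> np.ndarray:
        rr = inner * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        return center + rr * np.array([math.cos(th), math.sin(th)])

    pc = np.where(nucleus_mask, config.background, 0.0).astype(float)
    body_centers, body_masks = [], []
    for amp in config.body_amplitudes:
        c = random_interior()
        body_centers.append(c)
        g = np.exp(-((rows - (c[0] - center[0])) ** 2 +
                     (cols - (c[1] - center[1])) ** 2) / (2 * sigma_px ** 2))
        pc += amp * g * nucleus_mask
        body_masks.append((amp * g >= amp / 2.0) & nucleus_mask)
    body_centers_arr = (np.array(body_centers) if body_centers
                        else np.empty((0, 2)))

    fish = np.zeros((h, w), dtype=float)
    fish_centers, fish_in_body = [], []
    free_bodies = list(range(len(body_centers)))   # distinct bodies per spot
    for k in range(config.n_fish_spots):
        in_body = (len(free_bodies) > 0 and
                   rng.uniform() < config.fish_in_body_probability)
        if in_body:
            body = free_bodies.pop(int(rng.integers(len(free_bodies))))
            c = body_centers[body] + rng.uniform(-0.3, 0.3, size=2) * sigma_px
        else:
            c = random_interior()
        fish_centers.append(c)
        fish_in_body.append(bool(in_body))
        fish += config.fish_amplitude * np.exp(
            -((rows - (c[0] - center[0])) ** 2 +
              (cols - (c[1] - center[1])) ** 2) / (2 * sigma_px ** 2))
    fish_centers_arr = np.array(fish_centers)

    # noiseless truth: half-max region of each spot in the clean FISH channel
    truth_ratios = []
    nucleus_mean = pc[nucleus_mask].mean()
    for c in fish_centers:
        peak_rc = np.round(c).astype(int)
        peak_val = fish[peak_rc[0], peak_rc[1]]
        region = fish >= peak_val / 2.0
        # keep the connected component containing the peak
        from scipy import ndimage
        labels, _ = ndimage.label(region)
        region = labels == labels[peak_rc[0], peak_rc[1]]
        truth_ratios.append(float(pc[region].mean() / nucleus_mean))

    pc_noisy, fish_noisy = pc.copy(), fish.copy()
    if config.noise_sd > 0:
        pc_noisy += config.noise_sd * rng.standard_normal(pc.shape)
        fish_noisy += config.noise_sd * rng.standard_normal(fish.shape)

    return FishScene(pc_image=pc_noisy, fish_image=fish_noisy, clean_pc=pc,
                     clean_fish=fish, nucleus_mask=nucleus_mask,
                     body_masks=body_masks, body_centers_px=body_centers_arr,
                     fish_centers_px=fish_centers_arr, fish_in_body=fish_in_body,
                     truth_ratios=truth_ratios, config=config)
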