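"""Stage presets: parameter bundles for the motion simulator and analyses.

A :class:`StagePreset` collects everything that characterises one imaging
condition — a developmental stage, a marker (Polycomb body vs condensed
chromatin domain) and a temperature.  The numeric defaults encode the
measured conditions for *Drosophila* embryo nuclei: confinement radii of
290/200/140 nm for PC bodies and 180/160/90 nm for chromatin domains at
stages 5, 11 and 15, nuclear surfaces of 23/16/14 µm², and the short
time-lapse schedule of one frame every 250 ms for 15 s.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass


class InvalidConfigurationError(ValueError):
    """A simulator or analysis configuration violates its invariants."""


@dataclass(frozen=True)
class StagePreset:
    """Simulator/analysis parameters for one developmental stage.

    All lengths are in µm, times in s, intensities in arbitrary units.

    Parameters
    ----------
    stage_label
        Free-text label, e.g. ``"pc_stage11"``.
    nucleus_area_um2
        Average nuclear cross-section area.  The nucleus is modelled as a
        disc of radius ``sqrt(area / pi)``.
    n_bodies_per_nucleus
        Number of tracked objects (bodies or domains) per nucleus.
    confinement_radius_um
        Mean per-body confinement radius ``R_c``.  Each body moves as a 2D
        Ornstein–Uhlenbeck process whose per-axis stationary standard
        deviation is ``R_c / 2``, so the long-lag MSD plateau equals
        ``R_c**2``.
    confinement_radius_cv
        Log-normal coefficient of variation of per-body ``R_c`` around the
        mean (body-to-body heterogeneity).
    relaxation_time_s
        Time constant of the return-to-anchor force.  The MSD saturates
        within roughly three relaxation times.
    event_rate_per_s
        Poisson rate of long-range drift events, per group per second.
    event_speed_um_s
        Drift speed during a long-range event.
    event_duration_s
        Duration of one long-range event.
    n_groups_per_nucleus
        Number of higher-order structures ("groups"); all anchors of a
        group share its drift events.
    nucleus_drift_speed_um_s
        Whole-nucleus translation speed (random fixed direction).
    localization_noise_sd_um
        Per-axis Gaussian localisation error added to every sample.
    intensity_log_mean, intensity_log_sd
        Parameters of the log-normal body intensity distribution
        (natural-log scale).
    intensity_mobility_exponent
        Strength of the intensity–mobility anticorrelation: each body's
        ``R_c`` is scaled by ``(I / median I) ** -exponent``, renormalised
        so the ensemble mean-square radius is unchanged.
    frame_interval_s, n_frames
        Sampling schedule of the time-lapse.
    pixel_size_um
        Lateral pixel size used when rendering image stacks.
    temperature_factor
        Multiplier on motion amplitudes (OU sigma and event speed); 1.0 at
        25 °C, < 1 for colder embryos.
    """

    stage_label: str
    nucleus_area_um2: float
    n_bodies_per_nucleus: int = 10
    confinement_radius_um: float = 0.20
    confinement_radius_cv: float = 0.15
    relaxation_time_s: float = 1.0
    event_rate_per_s: float = 0.0277
    event_speed_um_s: float = 0.10
    event_duration_s: float = 10.0
    n_groups_per_nucleus: int = 6
    nucleus_drift_speed_um_s: float = 0.01
    localization_noise_sd_um: float = 0.015
    intensity_log_mean: float = 0.0
    intensity_log_sd: float = 0.6
    intensity_mobility_exponent: float = 0.4
    frame_interval_s: float = 0.25
    n_frames: int = 61
    pixel_size_um: float = 0.070
    temperature_factor: float = 1.0

    @property
    def nucleus_radius_um(self) -> float:
        return math.sqrt(self.nucleus_area_um2 / math.pi)

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s

    def validate(self) -> None:
        strictly_positive = {
            "nucleus_area_um2": self.nucleus_area_um2,
            "relaxation_time_s": self.relaxation_time_s,
            "event_duration_s": self.event_duration_s,
            "frame_interval_s": self.frame_interval_s,
            "pixel_size_um": self.pixel_size_um,
            "temperature_factor": self.temperature_factor,
            "intensity_log_sd": self.intensity_log_sd,
        }
        for name, value in strictly_positive.items():
            if not value > 0:
                raise InvalidConfigurationError(f"{name} must be > 0, got {value!r}")
        if self.n_frames < 1 or self.n_bodies_per_nucleus < 1:
            raise InvalidConfigurationError("n_frames and n_bodies_per_nucleus must be >= 1")
        if self.n_groups_per_nucleus < 1:
            raise InvalidConfigurationError("n_groups_per_nucleus must be >= 1")
        nonnegative = {
            "confinement_radius_um": self.confinement_radius_um,
            "confinement_radius_cv": self.confinement_radius_cv,
            "event_rate_per_s": self.event_rate_per_s,
            "event_speed_um_s": self.event_speed_um_s,
            "nucleus_drift_speed_um_s": self.nucleus_drift_speed_um_s,
            "localization_noise_sd_um": self.localization_noise_sd_um,
            "intensity_mobility_exponent": self.intensity_mobility_exponent,
        }
        for name, value in nonnegative.items():
            if value < 0:
                raise InvalidConfigurationError(f"{name} must be >= 0, got {value!r}")
        if self.confinement_radius_um >= self.nucleus_radius_um:
            raise InvalidConfigurationError(
                "nucleus radius must exceed the confinement radius "
                f"({self.nucleus_radius_um:.3f} <= {self.confinement_radius_um:.3f} um)"
            )

    def replace(self, **changes) -> "StagePreset":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def at_temperature(self, celsius: float) -> "StagePreset":
        """Preset variant for a different growth temperature.

        25 °C is the reference condition (factor 1.0); 18 °C slows both the
        local wobble and the long-range drift by a factor 0.7.
        """
        if celsius == 25:
            factor = 1.0
        elif celsius == 18:
            factor = 0.7
        else:
            raise InvalidConfigurationError(f"no temperature factor defined for {celsius} C")
        return self.replace(temperature_factor=factor,
                            stage_label=f"{self.stage_label}_{int(celsius)}C")


def _pc(stage: str, area: float, rc: float) -> StagePreset:
    return StagePreset(stage_label=f"pc_{stage}", nucleus_area_um2=area,
                       confinement_radius_um=rc, pixel_size_um=0.070,
                       localization_noise_sd_um=0.015)


def _chromatin(stage: str, area: float, rc: float) -> StagePreset:
    return StagePreset(stage_label=f"chromatin_{stage}", nucleus_area_um2=area,
                       confinement_radius_um=rc, pixel_size_um=0.048,
                       localization_noise_sd_um=0.012)


#: Default presets for PC bodies and condensed chromatin domains at
#: developmental stages 5, 11 and 15 (25 °C).
STAGE_PRESETS: dict[str, StagePreset] = {
    "pc_stage5": _pc("stage5", 23.0, 0.29),
    "pc_stage11": _pc("stage11", 16.0, 0.20),
    "pc_stage15": _pc("stage15", 14.0, 0.14),
    "chromatin_stage5": _chromatin("stage5", 23.0, 0.18),
    "chromatin_stage11": _chromatin("stage11", 16.0, 0.16),
    "chromatin_stage15": _chromatin("stage15", 14.0, 0.09),
    # long acquisition: one frame every 3 s for 3 min, used to see the
    # full confinement plateau of PC bodies
    "pc_stage11_long": _pc("stage11_long", 16.0, 0.20).replace(
        frame_interval_s=3.0, n_frames=61),
}


def get_preset(name: str) -> StagePreset:
    try:
        return STAGE_PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(STAGE_PRESETS))
        raise KeyError(f"unknown preset {name!r}; known presets: {known}") from None
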