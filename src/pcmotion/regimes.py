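"""Two-regime decomposition: constrained vs long-range, coordinated pairs.

The motion of nuclear bodies decomposes into a constitutive, locally
constrained wobble and occasional long-range drifts shared by groups of
objects.  Per track, the scatter of MSD/t at 3 s against the drop of
MSD/t between 3 s and 10 s separates the two: a pure plateau MSD gives
``y / x = (P/3 - P/10) / (P/3) = 0.7`` exactly, while a long-range
component keeps MSD/t from decaying and drives the ratio toward or below
zero.  Per pair, the ratio of MSC/t to the tracks' own MSD/t separates
coordinated motion (shared drift, distance barely changes) from
independent motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motion import MsdCurve, MscCurve, TTestResult, log_t_test, msd_over_t
from .tracks import Track, TrackSet

#: y/x of a track whose MSD has fully plateaued (see module docstring)
PLATEAU_RATIO = 0.7

#: default per-track threshold, between the plateau anchor (0.7) and the
#: long-range-dominated regime (<= 0); calibrated on labelled simulations
#: to balance the per-class error rates
DEFAULT_RATIO_THRESHOLD = 0.4

#: rho band calibrated on labelled simulated pairs: shared-drift pairs
#: concentrate near 0.1-0.2, while independently moving pairs (confined or
#: drifting apart) sit near or above 1; calls inside the band abstain
DEFAULT_RHO_COORDINATED = 0.2
DEFAULT_RHO_INDEPENDENT = 1.0


@dataclass
class RegimePoint:
    """Per-track regime coordinates (µm²/s)."""

    object_id: int
    x: float          # MSD/t at 3 s
    y: float          # MSD/t(3 s) - MSD/t(10 s)
    lag_early_s: float
    lag_late_s: float

    @property
    def ratio(self) -> float:
        return self.y / self.x if self.x > 0 else float("nan")


@dataclass
class RegimeLabel:
    object_id: int
    label: str        # "constrained" | "long_range" | "ambiguous"
    ratio: float


@dataclass
class PairClassification:
    pair: tuple[int, int]
    rho: float
    label: str        # "coordinated" | "independent" | "ambiguous"


def _resolve_lag(curve: MsdCurve, target_s: float, tol_s: float | None) -> int:
    if tol_s is None:
        spacing = np.min(np.diff(curve.lag_s)) if curve.lag_s.size > 1 else np.inf
        tol_s = spacing / 2
    idx = int(np.argmin(np.abs(curve.lag_s - target_s)))
    if abs(curve.lag_s[idx] - target_s) > tol_s + 1e-9:
        raise ValueError(f"no lag within {tol_s} s of {target_s} s")
    return idx


def regime_scatter(curves: list[MsdCurve], *, lag_early_s: float = 3.0,
                   lag_late_s: float = 10.0, tol_s: float | None = None
                   ) -> tuple[list[RegimePoint], list[int]]:
    """One (x, y) regime point per track; returns (points, skipped ids).

    The nominal 3 s and 10 s lags resolve to the nearest available lag
    within half a frame interval; tracks whose curves do not span both
    lags are skipped and reported.
    """
    points, skipped = [], []
    for curve in curves:
        try:
            i_early = _resolve_lag(curve, lag_early_s, tol_s)
            i_late = _resolve_lag(curve, lag_late_s, tol_s)
        except ValueError:
            skipped.append(curve.object_id)
            continue
        rate = msd_over_t(curve)
        x = float(rate.rate_um2_s[i_early])
        y = x - float(rate.rate_um2_s[i_late])
        points.append(RegimePoint(object_id=curve.object_id, x=x, y=y,
                                  lag_early_s=float(curve.lag_s[i_early]),
                                  lag_late_s=float(curve.lag_s[i_late])))
    return points, skipped


def classify_regime(points: list[RegimePoint], *,
                    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
                    ) -> list[RegimeLabel]:
    """Label each track constrained (y/x >= threshold) or long_range.

    A ratio exactly at the threshold counts as constrained; points with
    nonpositive x are labelled ambiguous.
    """
    labels = []
    for p in points:
        if not np.isfinite(p.x) or p.x <= 0:
            labels.append(RegimeLabel(p.object_id, "ambiguous", float("nan")))
            continue
        ratio = p.y / p.x
        label = "constrained" if ratio >= ratio_threshold else "long_range"
        labels.append(RegimeLabel(p.object_id, label, ratio))
    return labels


def classify_pair(msd_a: MsdCurve, msd_b: MsdCurve, msc: MscCurve, *,
                  window_s: tuple[float, float] = (3.0, 10.0),
                  rho_coordinated: float = DEFAULT_RHO_COORDINATED,
                  rho_independent: float = DEFAULT_RHO_INDEPENDENT
                  ) -> PairClassification:
    """Coordinated / independent / ambiguous call for one pair of tracks.

    rho = mean MSC/t over the window divided by the mean of the two
    tracks' mean MSD/t over the window.  A shared drift inflates MSD but
    leaves the pair distance nearly constant (rho -> 0); independently
    drifting objects change their distance at least as fast as they move
    (rho near or above 1).
    """
    lo, hi = window_s

    def window_mean(curve) -> float:
        mask = (curve.lag_s >= lo - 1e-9) & (curve.lag_s <= hi + 1e-9)
        if not mask.any():
            raise ValueError(f"curve does not cover the window {window_s}")
        return float(np.mean(curve.values[mask] / curve.lag_s[mask]))

    msd_mean = 0.5 * (window_mean(msd_a) + window_mean(msd_b))
    msc_mean = window_mean(msc)
    pair = (msd_a.object_id, msd_b.object_id)
    if msd_mean <= 0:
        return PairClassification(pair=pair, rho=float("nan"), label="ambiguous")
    rho = msc_mean / msd_mean
    if rho <= rho_coordinated:
        label = "coordinated"
    elif rho >= rho_independent:
        label = "independent"
    else:
        label = "ambiguous"
    return PairClassification(pair=pair, rho=rho, label=label)


@dataclass
class IntensityComparison:
    """MSD/t of the brighter vs fainter object of each nucleus."""

    intense_values: np.ndarray
    weak_values: np.ndarray
    test: TTestResult
    lag_s: float
    excluded_nuclei: list[int]


def intensity_stratified_comparison(trackset: TrackSet | list[Track],
                                    msd_curves: dict[int, MsdCurve], *,
                                    lag_s: float = 1.0) -> IntensityComparison:
    """Compare mobility of the most vs least intense body per nucleus.

    Requires exactly two tracked objects per nucleus (others are excluded
    and reported).  Per nucleus the track with the higher mean intensity
    joins the "intense" group (ties go to the lower object id); the Welch
    t-test on log MSD/t at ``lag_s`` compares the two groups.
    """
    tracks = list(trackset.tracks) if isinstance(trackset, TrackSet) else list(trackset)
    by_nucleus: dict[int, list[Track]] = {}
    for tr in tracks:
        by_nucleus.setdefault(tr.nucleus_id, []).append(tr)
    intense, weak, excluded = [], [], []
    for nid, members in sorted(by_nucleus.items()):
        if len(members) != 2:
            excluded.append(nid)
            continue
        a, b = sorted(members, key=lambda t: t.object_id)
        ia, ib = a.mean_intensity(), b.mean_intensity()
        bright, faint = (a, b) if ia >= ib else (b, a)
        values = []
        for tr in (bright, faint):
            curve = msd_curves[tr.object_id]
            idx = _resolve_lag(curve, lag_s, None)
            values.append(float(curve.values[idx] / curve.lag_s[idx]))
        intense.append(values[0])
        weak.append(values[1])
    if len(intense) < 2:
        raise ValueError("need at least two nuclei with exactly two tracks each")
    intense_arr, weak_arr = np.asarray(intense), np.asarray(weak)
    return IntensityComparison(intense_values=intense_arr, weak_values=weak_arr,
                               test=log_t_test(intense_arr, weak_arr),
                               lag_s=lag_s, excluded_nuclei=excluded)
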