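"""Core trajectory statistics: MSD, MSC, angles, radii and tests.

Definitions
-----------
MSD(Δ)
    mean over all ordered same-track sample pairs separated by lag Δ of
    the squared Euclidean displacement (time-averaged, overlapping
    pairs).  Computed on nucleus-centred ("relative") coordinates.
MSC(Δ)
    with d(t) the scalar distance between two objects, the mean over t of
    ``(d(t+Δ) - d(t))**2``.  Computed on absolute coordinates: a common
    drift of the whole nucleus cancels in d(t) by construction.
Turning (vertex) angle
    angle at the middle point of three consecutive samples spaced by one
    lag: 180° is a straight continuation, 0° a full reversal; uniform on
    [0°, 180°] for an isotropic planar random walk.
Confinement radius
    square root of the MSD plateau, the radius of the region an object
    effectively explores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .tracks import Track, common_frames


@dataclass
class MsdCurve:
    """Lag-indexed mean-square displacement with sample counts."""

    lag_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    object_id: int | None = None
    mode: str = "relative"
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)

    @property
    def values(self) -> np.ndarray:
        return self.msd_um2


@dataclass
class MscCurve:
    """Lag-indexed mean-square change in pair distance."""

    lag_s: np.ndarray
    msc_um2: np.ndarray
    n_pairs: np.ndarray
    pair: tuple[int, int] = (-1, -1)
    mode: str = "absolute"

    def __post_init__(self) -> None:
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.msc_um2 = np.asarray(self.msc_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)

    @property
    def values(self) -> np.ndarray:
        return self.msc_um2


@dataclass
class RateCurve:
    """MSD/t or MSC/t values against lag (µm²/s)."""

    lag_s: np.ndarray
    rate_um2_s: np.ndarray
    n_pairs: np.ndarray
    object_id: int | None = None


@dataclass
class AngleHistogram:
    """Relative frequency of turning angles over [0°, 180°]."""

    bin_edges_deg: np.ndarray
    frequency: np.ndarray
    lag_s: float
    n_angles: int
    n_zero_skipped: int = 0


@dataclass
class RadiusEstimate:
    """Confinement radius from an MSD plateau (radius = sqrt(plateau))."""

    radius_um: float
    plateau_um2: float
    window_s: tuple[float, float]


def _lag_indices(track: Track, lags_s: np.ndarray | None) -> tuple[np.ndarray, list[str]]:
    dt = track.frame_interval_s
    n = track.n_frames
    notes: list[str] = []
    if lags_s is None:
        ks = np.arange(1, n)
    else:
        ks, kept = [], []
        for lag in np.atleast_1d(lags_s):
            k = int(round(lag / dt))
            if abs(k * dt - lag) > dt / 2 or k < 1:
                notes.append(f"lag {lag} s is not a multiple of the frame interval")
                continue
            if k > n - 1:
                notes.append(f"lag {lag} s exceeds the track span; omitted")
                continue
            ks.append(k)
        ks = np.array(sorted(set(ks)), dtype=int)
    return np.asarray(ks, dtype=int), notes


def compute_msd(track: Track, lags_s: np.ndarray | None = None, *,
                mode: str = "relative") -> MsdCurve:
    """Time-averaged MSD of one track over overlapping pairs.

    ``lags_s=None`` uses every available lag.  Lags that exceed the track
    span are omitted and recorded in ``curve.notes``.
    """
    if track.n_frames < 2:
        raise ValueError("MSD needs at least two samples")
    dt = track.frame_interval_s
    ks, notes = _lag_indices(track, lags_s)
    pos = track.xy_um
    msd = np.empty(ks.shape[0])
    counts = np.empty(ks.shape[0], dtype=int)
    for i, k in enumerate(ks):
        disp = pos[k:] - pos[:-k]
        msd[i] = np.mean(np.sum(disp * disp, axis=1))
        counts[i] = disp.shape[0]
    return MsdCurve(lag_s=ks * dt, msd_um2=msd, n_pairs=counts,
                    object_id=track.object_id, mode=mode, notes=notes)


def compute_msc(track_a: Track, track_b: Track,
                lags_s: np.ndarray | None = None) -> MscCurve:
    """Mean square change of the scalar distance between two objects.

    Both tracks must cover the same frames; absolute (drift-uncorrected)
    coordinates are the intended input.
    """
    common_frames([track_a, track_b])
    dt = track_a.frame_interval_s
    ks, _ = _lag_indices(track_a, lags_s)
    d = np.linalg.norm(track_a.xy_um[:, :2] - track_b.xy_um[:, :2], axis=1)
    msc = np.empty(ks.shape[0])
    counts = np.empty(ks.shape[0], dtype=int)
    for i, k in enumerate(ks):
        delta = d[k:] - d[:-k]
        msc[i] = np.mean(delta * delta)
        counts[i] = delta.shape[0]
    return MscCurve(lag_s=ks * dt, msc_um2=msc, n_pairs=counts,
                    pair=(track_a.object_id, track_b.object_id))


def ensemble_curve(curves: list[MsdCurve]) -> MsdCurve:
    """Unweighted mean of per-track curves on their common lag grid."""
    if not curves:
        raise ValueError("no curves to average")
    common = curves[0].lag_s
    for c in curves[1:]:
        mask = np.isin(np.round(common, 9), np.round(c.lag_s, 9))
        common = common[mask]
    if common.size == 0:
        raise ValueError("curves share no common lag")
    stackv, stackn = [], []
    for c in curves:
        idx = np.nonzero(np.isin(np.round(c.lag_s, 9), np.round(common, 9)))[0]
        stackv.append(c.values[idx])
        stackn.append(c.n_pairs[idx])
    return MsdCurve(lag_s=common, msd_um2=np.mean(stackv, axis=0),
                    n_pairs=np.sum(stackn, axis=0), object_id=None,
                    mode=curves[0].mode)


def msd_over_t(curve: MsdCurve | MscCurve) -> RateCurve:
    """Element-wise MSD(Δ)/Δ (or MSC/Δ); flat for free diffusion."""
    if np.any(curve.lag_s <= 0):
        raise ValueError("all lags must be positive")
    oid = getattr(curve, "object_id", None)
    return RateCurve(lag_s=curve.lag_s.copy(),
                     rate_um2_s=curve.values / curve.lag_s,
                     n_pairs=curve.n_pairs.copy(), object_id=oid)


def turning_angles(track: Track, lag_s: float) -> tuple[np.ndarray, int]:
    """Vertex angles (degrees) between consecutive equal-lag displacements.

    Returns ``(angles, n_zero_skipped)``; triplets containing a zero-length
    displacement are skipped and counted.
    """
    dt = track.frame_interval_s
    k = int(round(lag_s / dt))
    if k < 1 or abs(k * dt - lag_s) > dt / 2:
        raise ValueError(f"lag {lag_s} s is not available at a {dt} s interval")
    pos = track.xy_um[:, :2]
    if pos.shape[0] < 2 * k + 1:
        return np.empty(0), 0
    p0, p1, p2 = pos[:-2 * k], pos[k:-k], pos[2 * k:]
    u = p0 - p1     # back toward the previous point
    v = p2 - p1     # forward to the next point
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > 0) & (nv > 0)
    cosang = np.sum(u[ok] * v[ok], axis=1) / (nu[ok] * nv[ok])
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return angles, int((~ok).sum())


def turning_angle_histogram(tracks: list[Track], lag_s: float, *,
                            bin_width_deg: float = 30.0) -> AngleHistogram:
    """Histogram of vertex angles pooled over tracks (frequencies sum to 1)."""
    all_angles, skipped = [], 0
    for tr in tracks:
        ang, nskip = turning_angles(tr, lag_s)
        all_angles.append(ang)
        skipped += nskip
    angles = np.concatenate(all_angles) if all_angles else np.empty(0)
    edges = np.arange(0.0, 180.0 + bin_width_deg / 2, bin_width_deg)
    if angles.size == 0:
        warnings.warn("no nonzero displacements: empty angle histogram",
                      stacklevel=2)
        freq = np.zeros(edges.size - 1)
    else:
        counts, _ = np.histogram(angles, bins=edges)
        freq = counts / counts.sum()
    return AngleHistogram(bin_edges_deg=edges, frequency=freq, lag_s=lag_s,
                          n_angles=int(angles.size), n_zero_skipped=skipped)


def confinement_radius(curve: MsdCurve, window_s: tuple[float, float] = (3.0, 10.0)
                       ) -> RadiusEstimate:
    """Confinement radius as the square root of the mean MSD in a window.

    The default 3–10 s window suits short acquisitions; long acquisitions
    that resolve the full plateau use 60–120 s.
    """
    lo, hi = window_s
    mask = (curve.lag_s >= lo - 1e-9) & (curve.lag_s <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"curve does not cover the window {window_s}")
    plateau = float(np.mean(curve.values[mask]))
    return RadiusEstimate(radius_um=math.sqrt(max(plateau, 0.0)),
                          plateau_um2=plateau, window_s=(lo, hi))


def radius_at_lag(curve: MsdCurve, lag_s: float) -> float:
    """sqrt(MSD(lag)): the radius explored within one lag time."""
    idx = np.nonzero(np.abs(curve.lag_s - lag_s) < 1e-9)[0]
    if idx.size == 0:
        raise ValueError(f"lag {lag_s} s is absent from the curve")
    return float(math.sqrt(max(curve.values[idx[0]], 0.0)))


def territory_radius(nucleus_area_um2: float, n_arms: int = 10) -> float:
    """Radius of one chromosome-arm territory from the nuclear area.

    The arm territory is approximated as a disc of area
    ``nucleus_area / n_arms`` (the tiny 4th chromosome is not counted);
    the result is reported rounded to 10 nm.
    """
    if nucleus_area_um2 <= 0 or n_arms < 1:
        raise ValueError("area must be positive and n_arms >= 1")
    return round(math.sqrt(nucleus_area_um2 / (n_arms * math.pi)), 2)


@dataclass
class CorrelationResult:
    r: float
    pvalue: float
    n: int


def msd_msc_correlation(msd_values: np.ndarray, msc_values: np.ndarray
                        ) -> CorrelationResult:
    """Pearson correlation of log MSD vs log MSC at a fixed lag.

    Both statistics are log-normally distributed across objects, so the
    correlation (and its two-sided p-value) is computed on natural logs.
    """
    x = np.log(np.asarray(msd_values, dtype=float))
    y = np.log(np.asarray(msc_values, dtype=float))
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance samples")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), pvalue=float(res.pvalue),
                             n=x.size)


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """max |ECDF_A - ECDF_B| over the pooled sample points."""
    a = np.sort(a)
    b = np.sort(b)
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.max(np.abs(cdf_a - cdf_b)))


@dataclass
class KsResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    method: str


def two_sample_ks(sample_a: np.ndarray, sample_b: np.ndarray, *,
                  method: str = "auto", n_permutations: int = 10_000,
                  seed: int | None = None) -> KsResult:
    """Two-sample Kolmogorov–Smirnov test, D = max |ECDF_A - ECDF_B|.

    ``method="asymp"`` uses the asymptotic Kolmogorov distribution;
    ``"permutation"`` estimates the p-value by label permutation;
    ``"auto"`` permutes below a combined sample size of 100 and is
    asymptotic otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if method == "auto":
        method = "permutation" if a.size + b.size < 100 else "asymp"
    d = float(stats.ks_2samp(a, b, method="asymp").statistic)
    if method == "asymp":
        # survival function of the Kolmogorov distribution at sqrt(n)·D
        en = math.sqrt(a.size * b.size / (a.size + b.size))
        p = float(special.kolmogorov(en * d))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        combined = np.concatenate([a, b])
        count = 0
        for _ in range(n_permutations):
            rng.shuffle(combined)
            if _ks_statistic(combined[:a.size], combined[a.size:]) >= d - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KsResult(statistic=d, pvalue=p, n_a=a.size, n_b=b.size, method=method)


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int


def log_t_test(sample_a: np.ndarray, sample_b: np.ndarray) -> TTestResult:
    """Welch two-sample t-test on natural logs.

    The appropriate comparison for log-normally distributed quantities
    such as per-object MSD and MSC values; all values must be positive.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per sample")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("log t-test requires strictly positive values")
    res = stats.ttest_ind(np.log(a), np.log(b), equal_var=False)
    return TTestResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                       n_a=a.size, n_b=b.size)
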