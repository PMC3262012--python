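"""Track containers and the delimited track-table format.

A :class:`Track` is one object's time-ordered positions (µm) and
intensities within one nucleus.  A :class:`TrackSet` bundles the tracks of
an experiment together with per-nucleus centre-of-mass traces.  Track
tables are tab-delimited text with the header columns
``nucleus_id, object_id, group_id, channel, frame, t_s, x_um, y_um, z_um,
intensity`` (``z_um`` blank for 2D data); unknown extra columns survive a
read/write round trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["nucleus_id", "object_id", "group_id", "channel",
                    "frame", "t_s", "x_um", "y_um", "z_um", "intensity"]

#: tolerance on uniformity of the time step, in seconds
TIME_STEP_TOL_S = 1e-6


class SchemaError(ValueError):
    """A track table is missing a required column."""


@dataclass
class Track:
    """Time-ordered positions and intensities of one tracked object."""

    object_id: int
    nucleus_id: int
    t_s: np.ndarray
    xy_um: np.ndarray            # shape (n, 2) or (n, 3)
    intensity: np.ndarray | None = None
    group_id: int | None = None
    channel: int = 0

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.xy_um = np.asarray(self.xy_um, dtype=float)
        if self.xy_um.ndim != 2 or self.xy_um.shape[1] not in (2, 3):
            raise ValueError("xy_um must have shape (n, 2) or (n, 3)")
        if self.xy_um.shape[0] != self.t_s.shape[0]:
            raise ValueError("t_s and xy_um lengths differ")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.intensity.shape[0] != self.t_s.shape[0]:
                raise ValueError("intensity length differs from t_s")

    @property
    def n_frames(self) -> int:
        return self.t_s.shape[0]

    @property
    def ndim(self) -> int:
        return self.xy_um.shape[1]

    @property
    def frame_interval_s(self) -> float:
        """Uniform time step; raises if spacing varies beyond tolerance."""
        steps = np.diff(self.t_s)
        if steps.size == 0:
            raise ValueError("track has a single sample, no time step")
        if np.ptp(steps) > TIME_STEP_TOL_S:
            raise ValueError("track is not uniformly sampled")
        return float(steps.mean())

    def mean_intensity(self) -> float:
        if self.intensity is None:
            raise ValueError(f"track {self.object_id} carries no intensity")
        return float(np.mean(self.intensity))

    def with_positions(self, xy_um: np.ndarray) -> "Track":
        return Track(object_id=self.object_id, nucleus_id=self.nucleus_id,
                     t_s=self.t_s.copy(), xy_um=np.asarray(xy_um, dtype=float),
                     intensity=None if self.intensity is None else self.intensity.copy(),
                     group_id=self.group_id, channel=self.channel)


@dataclass
class NucleusTrace:
    """Per-frame centre of mass and area of one nucleus."""

    nucleus_id: int
    t_s: np.ndarray
    center_um: np.ndarray        # shape (n, 2)
    area_um2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.center_um = np.asarray(self.center_um, dtype=float)
        if self.center_um.shape != (self.t_s.shape[0], 2):
            raise ValueError("center_um must have shape (n_frames, 2)")


@dataclass
class TrackSet:
    """Tracks of one experiment, plus optional nucleus traces."""

    tracks: list[Track]
    nucleus_traces: dict[int, NucleusTrace] = field(default_factory=dict)
    extra_columns: pd.DataFrame | None = None   # preserved unknown columns

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __len__(self) -> int:
        return len(self.tracks)

    def by_nucleus(self) -> dict[int, list[Track]]:
        out: dict[int, list[Track]] = {}
        for tr in self.tracks:
            out.setdefault(tr.nucleus_id, []).append(tr)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per object per frame."""
        parts = []
        for tr in self.tracks:
            n = tr.n_frames
            part = pd.DataFrame({
                "nucleus_id": np.full(n, tr.nucleus_id, dtype=int),
                "object_id": np.full(n, tr.object_id, dtype=int),
                "group_id": np.full(n, -1 if tr.group_id is None else tr.group_id,
                                    dtype=int),
                "channel": np.full(n, tr.channel, dtype=int),
                "frame": np.arange(n, dtype=int),
                "t_s": tr.t_s,
                "x_um": tr.xy_um[:, 0],
                "y_um": tr.xy_um[:, 1],
                "z_um": tr.xy_um[:, 2] if tr.ndim == 3 else np.full(n, np.nan),
                "intensity": (tr.intensity if tr.intensity is not None
                              else np.full(n, np.nan)),
            })
            parts.append(part)
        frame = pd.concat(parts, ignore_index=True)
        if self.extra_columns is not None and len(self.extra_columns) == len(frame):
            frame = pd.concat([frame, self.extra_columns.reset_index(drop=True)], axis=1)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrackSet":
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"track table is missing required column(s): "
                              f"{', '.join(missing)}")
        tracks = []
        for (nid, oid), sub in frame.groupby(["nucleus_id", "object_id"], sort=True):
            sub = sub.sort_values("frame")
            t = sub["t_s"].to_numpy(dtype=float)
            steps = np.diff(t)
            if steps.size and np.ptp(steps) > TIME_STEP_TOL_S:
                warnings.warn(f"track {oid} in nucleus {nid}: non-uniform time step",
                              stacklevel=2)
            z = sub["z_um"].to_numpy(dtype=float)
            if np.all(np.isnan(z)):
                xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
            else:
                xy = sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
            inten = sub["intensity"].to_numpy(dtype=float)
            gid = int(sub["group_id"].iloc[0])
            tracks.append(Track(
                object_id=int(oid), nucleus_id=int(nid), t_s=t, xy_um=xy,
                intensity=None if np.all(np.isnan(inten)) else inten,
                group_id=None if gid < 0 else gid,
                channel=int(sub["channel"].iloc[0])))
        extra_cols = [c for c in frame.columns if c not in REQUIRED_COLUMNS]
        extra = None
        if extra_cols:
            order = frame.sort_values(["nucleus_id", "object_id", "frame"])
            extra = order[extra_cols].reset_index(drop=True)
        return cls(tracks=tracks, extra_columns=extra)


def write_tracks(trackset: TrackSet, path: str | Path) -> None:
    """Write a tab-delimited track table (see module docstring for schema)."""
    trackset.to_frame().to_csv(path, sep="\t", index=False, na_rep="")


def read_tracks(path: str | Path) -> TrackSet:
    """Read a tab-delimited track table; errors name any missing column."""
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return TrackSet.from_frame(frame)


def uniform_times(n_frames: int, frame_interval_s: float) -> np.ndarray:
    return np.arange(n_frames, dtype=float) * frame_interval_s


def common_frames(tracks: Sequence[Track]) -> None:
    """Raise if the tracks do not share a common time grid."""
    ref = tracks[0].t_s
    for tr in tracks[1:]:
        if tr.t_s.shape != ref.shape or np.any(np.abs(tr.t_s - ref) > TIME_STEP_TOL_S):
            raise ValueError(
                f"tracks {tracks[0].object_id} and {tr.object_id} do not cover "
                "the same frames")
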