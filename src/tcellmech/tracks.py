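"""Migration-track analytics for cells crawling on elastic substrates.

Works on 2D time-lapse trajectories (one position per frame, positions in
µm, times in s) as exported by spot-tracking tools. Three quantities are
computed per track:

* instantaneous speeds — per-frame step length over step duration, in µm/min;
* maximum excursion — the largest Euclidean distance between *any* two
  points of the track (not net displacement, not path length);
* an arrested/migrating call — a cell is arrested when its maximum
  excursion over a 5-min observation window stays strictly below 10 µm,
  i.e. below an excursion rate of 2 µm/min. For tracks of non-standard
  duration the distance threshold scales linearly with duration so the
  2 µm/min rate is preserved.

Cohort summaries report the fraction of arrested cells and velocity
statistics over the migrating cells only (the convention used when
reporting "velocities of migrating cells"); all-track statistics are
exposed alongside for deceleration-style analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "Track",
    "TrackMetrics",
    "CohortSummary",
    "instantaneous_speeds",
    "max_excursion",
    "net_displacement",
    "classify_arrest",
    "track_metrics",
    "summarize_cohort",
    "DEFAULT_ARREST_THRESHOLD_UM",
    "DEFAULT_ARREST_WINDOW_S",
    "MIN_POINTS_FOR_VELOCITY",
]

log = logging.getLogger(__name__)

#: Arrest rule: maximum excursion below this distance ...
DEFAULT_ARREST_THRESHOLD_UM = 10.0
#: ... over this observation window (5 min), i.e. < 2 µm/min.
DEFAULT_ARREST_WINDOW_S = 300.0
#: Tracks with fewer points are excluded from cohort velocity statistics.
MIN_POINTS_FOR_VELOCITY = 3
#: Relative tolerance for the frame-interval uniformity check.
FRAME_INTERVAL_RTOL = 1e-6


@dataclass(frozen=True)
class Track:
    """Time-ordered 2D positions of one cell.

    Parameters
    ----------
    track_id
        Opaque identifier (kept as given).
    times
        Acquisition times in seconds, strictly increasing.
    xs, ys
        Positions in µm.

    Irregular frame intervals are tolerated (speeds always use per-step
    durations) but logged as a warning, since a uniform interval is the
    normal acquisition mode (one frame every few seconds).
    """

    track_id: str
    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        xs = np.asarray(self.xs, dtype=float)
        ys = np.asarray(self.ys, dtype=float)
        if not (len(times) == len(xs) == len(ys)):
            raise ValueError(
                f"track {self.track_id!r}: times/xs/ys lengths differ "
                f"({len(times)}/{len(xs)}/{len(ys)})"
            )
        if len(times) < 1:
            raise ValueError(f"track {self.track_id!r}: empty track")
        if len(times) > 1:
            dts = np.diff(times)
            if np.any(dts <= 0):
                raise ValueError(
                    f"track {self.track_id!r}: times not strictly increasing"
                )
            if not np.allclose(dts, dts[0], rtol=FRAME_INTERVAL_RTOL, atol=0.0):
                log.warning(
                    "track %r: irregular frame interval (min %.6g s, max %.6g s); "
                    "per-step durations will be used",
                    self.track_id,
                    dts.min(),
                    dts.max(),
                )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "ys", ys)

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Track duration in seconds."""
        return float(self.times[-1] - self.times[0])

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of positions in µm."""
        return np.column_stack([self.xs, self.ys])


@dataclass(frozen=True)
class TrackMetrics:
    """Per-track summary: mean speed, excursion and the arrest call."""

    track_id: str
    n_points: int
    duration_s: float
    mean_velocity_um_min: float
    max_excursion_um: float
    arrested: bool


@dataclass(frozen=True)
class CohortSummary:
    """Per-condition aggregate over a collection of tracks.

    Velocity statistics (``velocity_mean``/``velocity_sem``) are computed
    over the per-track mean instantaneous velocities of *migrating* tracks
    only; ``velocity_defined`` is False (and the values NaN) when the
    cohort has no usable migrating track. All-track velocity statistics
    and the excursion distribution over all tracks are reported alongside.
    """

    n_tracks: int
    n_arrested: int
    percent_arrested: float
    velocity_mean: float
    velocity_sem: float
    velocity_defined: bool
    n_velocity_tracks: int
    velocity_mean_all: float
    velocity_sem_all: float
    excursion_mean: float
    excursion_sem: float
    excursion_min: float
    excursion_max: float
    n_excluded_short: int = 0


def instantaneous_speeds(track: Track) -> np.ndarray:
    """Per-step speeds of a track in µm/min.

    Element ``i`` is the Euclidean distance between points ``i`` and
    ``i+1`` divided by the step duration; the result has ``n_points - 1``
    elements. Raises ``ValueError`` for single-point tracks.
    """
    if track.n_points < 2:
        raise ValueError(f"track {track.track_id!r} too short: need >= 2 points")
    steps = np.hypot(np.diff(track.xs), np.diff(track.ys))
    dts = np.diff(track.times)
    return steps / dts * 60.0


def max_excursion(track: Track) -> float:
    """Maximum pairwise Euclidean distance within a track, in µm.

    This is the "maximum distance traveled" statistic: the largest
    separation between any two points of the track. A single-point track
    has excursion 0.
    """
    if track.n_points < 2:
        return 0.0
    return float(pdist(track.positions).max())


def net_displacement(track: Track) -> float:
    """Start-to-end Euclidean distance in µm (always <= max_excursion)."""
    return float(
        math.hypot(track.xs[-1] - track.xs[0], track.ys[-1] - track.ys[0])
    )


def classify_arrest(
    track: Track,
    threshold_um: float = DEFAULT_ARREST_THRESHOLD_UM,
    window_s: float = DEFAULT_ARREST_WINDOW_S,
) -> bool:
    """Arrested/migrating call for one track.

    A cell is arrested when its maximum excursion is *strictly* below the
    distance threshold for the observation window (10 µm per 5 min, i.e.
    2 µm/min); an excursion exactly at the threshold is migrating. Tracks
    whose duration differs from ``window_s`` use a linearly scaled
    threshold ``threshold_um * duration / window_s``, preserving the rate.
    """
    if threshold_um <= 0 or window_s <= 0:
        raise ValueError("threshold_um and window_s must be positive")
    if track.duration <= 0:
        raise ValueError(
            f"track {track.track_id!r}: zero-duration track cannot be classified"
        )
    effective = threshold_um * track.duration / window_s
    return max_excursion(track) < effective


def track_metrics(
    track: Track,
    threshold_um: float = DEFAULT_ARREST_THRESHOLD_UM,
    window_s: float = DEFAULT_ARREST_WINDOW_S,
) -> TrackMetrics:
    """Compute the per-track summary (speed, excursion, arrest call)."""
    return TrackMetrics(
        track_id=track.track_id,
        n_points=track.n_points,
        duration_s=track.duration,
        mean_velocity_um_min=float(np.mean(instantaneous_speeds(track))),
        max_excursion_um=max_excursion(track),
        arrested=classify_arrest(track, threshold_um, window_s),
    )


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    if len(values) > 1:
        sem = float(np.std(values, ddof=1) / math.sqrt(len(values)))
    else:
        sem = float("nan")
    return mean, sem


def summarize_cohort(
    tracks: Iterable[Track],
    threshold_um: float = DEFAULT_ARREST_THRESHOLD_UM,
    window_s: float = DEFAULT_ARREST_WINDOW_S,
    min_points: int = MIN_POINTS_FOR_VELOCITY,
) -> CohortSummary:
    """Aggregate a collection of tracks into a cohort summary.

    ``percent_arrested`` counts every classifiable track; velocity
    statistics use the per-track mean instantaneous velocity of migrating
    tracks with at least ``min_points`` points (shorter tracks are
    excluded from the velocity statistics and logged).
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("empty track collection")

    arrested_flags = []
    excursions = []
    migrating_speeds = []
    all_speeds = []
    n_excluded = 0
    for tr in tracks:
        arrested = classify_arrest(tr, threshold_um, window_s)
        arrested_flags.append(arrested)
        excursions.append(max_excursion(tr))
        if tr.n_points < min_points:
            n_excluded += 1
            log.info(
                "track %r excluded from velocity statistics (%d points < %d)",
                tr.track_id,
                tr.n_points,
                min_points,
            )
            continue
        v = float(np.mean(instantaneous_speeds(tr)))
        all_speeds.append(v)
        if not arrested:
            migrating_speeds.append(v)

    n_tracks = len(tracks)
    n_arrested = int(sum(arrested_flags))
    excursions = np.asarray(excursions)
    exc_mean, exc_sem = _mean_sem(excursions)

    if migrating_speeds:
        v_mean, v_sem = _mean_sem(np.asarray(migrating_speeds))
        defined = True
    else:
        v_mean = v_sem = float("nan")
        defined = False
        log.warning("cohort has no migrating tracks: velocity statistics undefined")

    if all_speeds:
        v_mean_all, v_sem_all = _mean_sem(np.asarray(all_speeds))
    else:
        v_mean_all = v_sem_all = float("nan")

    return CohortSummary(
        n_tracks=n_tracks,
        n_arrested=n_arrested,
        percent_arrested=100.0 * n_arrested / n_tracks,
        velocity_mean=v_mean,
        velocity_sem=v_sem,
        velocity_defined=defined,
        n_velocity_tracks=len(migrating_speeds),
        velocity_mean_all=v_mean_all,
        velocity_sem_all=v_sem_all,
        excursion_mean=exc_mean,
        excursion_sem=exc_sem,
        excursion_min=float(excursions.min()),
        excursion_max=float(excursions.max()),
        n_excluded_short=n_excluded,
    )
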