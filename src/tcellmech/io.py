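"""Readers and writers for the toolkit's tabular formats.

Tracks come in as the spot-table CSV dialect of common tracking-tool
exports (one row per spot: TRACK_ID, POSITION_X, POSITION_Y and either
POSITION_T in seconds or FRAME plus a frame interval). Force curves come
in either raw (``D_um``, ``d_um``) or processed (``delta_um``, ``F_nN``)
columns, auto-detected from the header; an optional ``curve_id`` column
holds multiple curves in long format. All CSVs are comma-separated,
dot-decimal, with a mandatory header row. Structured outputs are JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .indentation import ForceCurve, HertzFitResult
from .rheology import RheologySweep
from .tracks import CohortSummary, Track, TrackMetrics

__all__ = [
    "DEFAULT_TRACK_COLUMNS",
    "read_tracks",
    "read_force_curves",
    "read_sweeps",
    "write_tracks",
    "write_track_metrics",
    "write_cohort_summary",
    "write_force_curve",
    "write_fit_results",
    "write_sweep",
]

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

DEFAULT_TRACK_COLUMNS: Dict[str, str] = {
    "track_id": "TRACK_ID",
    "x": "POSITION_X",
    "y": "POSITION_Y",
    "t": "POSITION_T",
    "frame": "FRAME",
    "z": "POSITION_Z",
}

RAW_CURVE_COLUMNS = ("D_um", "d_um")
PROCESSED_CURVE_COLUMNS = ("delta_um", "F_nN")


def read_tracks(
    path: PathLike,
    column_map: Optional[Mapping[str, str]] = None,
    dt: Optional[float] = None,
) -> List[Track]:
    """Read a spot-table CSV into Tracks, grouped by id and sorted by time.

    Times come from the ``t`` column (seconds) when present; otherwise the
    ``frame`` column is converted via ``dt`` (seconds per frame). Any z
    column is ignored with a warning (positions are 2D). Duplicate
    (track, time) rows are an error.
    """
    cols = {**DEFAULT_TRACK_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path)

    for key in ("track_id", "x", "y"):
        if cols[key] not in df.columns:
            raise ValueError(f"missing mapped column {cols[key]!r} (for {key})")
    if cols["z"] in df.columns:
        log.warning("ignoring z column %r: positions are treated as 2D", cols["z"])

    if cols["t"] in df.columns:
        times = df[cols["t"]].astype(float)
    elif cols["frame"] in df.columns:
        if dt is None:
            raise ValueError(
                f"file has a {cols['frame']!r} column but no {cols['t']!r}; "
                "a frame interval dt is required"
            )
        times = df[cols["frame"]].astype(float) * dt
    else:
        raise ValueError(
            f"missing time information: need column {cols['t']!r} or "
            f"{cols['frame']!r} (with dt)"
        )

    work = pd.DataFrame(
        {
            "track_id": df[cols["track_id"]],
            "t": times,
            "x": df[cols["x"]].astype(float),
            "y": df[cols["y"]].astype(float),
        }
    )
    dup = work.duplicated(subset=["track_id", "t"])
    if dup.any():
        first = work[dup].iloc[0]
        raise ValueError(
            f"duplicate (track, time) rows, e.g. track {first['track_id']!r} "
            f"at t={first['t']}"
        )

    tracks = []
    for track_id, grp in work.groupby("track_id", sort=True):
        grp = grp.sort_values("t")
        tracks.append(
            Track(
                track_id=str(track_id),
                times=grp["t"].to_numpy(),
                xs=grp["x"].to_numpy(),
                ys=grp["y"].to_numpy(),
            )
        )
    log.info("read %d tracks (%d spots) from %s", len(tracks), len(work), path)
    return tracks


def write_tracks(tracks: Iterable[Track], path: PathLike, dt: Optional[float] = None) -> None:
    """Write tracks back to the spot-table CSV dialect."""
    rows = []
    for tr in tracks:
        for t, x, y in zip(tr.times, tr.xs, tr.ys):
            rows.append({"TRACK_ID": tr.track_id, "POSITION_T": t, "POSITION_X": x, "POSITION_Y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_force_curves(path: PathLike) -> List[ForceCurve]:
    """Read force curves, auto-detecting the raw vs processed dialect.

    Raw files carry columns ``D_um, d_um``; processed files carry
    ``delta_um, F_nN``. A file with both (or neither) set of columns is
    rejected. Without a ``curve_id`` column the file is a single curve.
    """
    df = pd.read_csv(path)
    has_raw = all(c in df.columns for c in RAW_CURVE_COLUMNS)
    has_proc = all(c in df.columns for c in PROCESSED_CURVE_COLUMNS)
    if has_raw and has_proc:
        raise ValueError(
            f"ambiguous header in {path}: both raw {RAW_CURVE_COLUMNS} and "
            f"processed {PROCESSED_CURVE_COLUMNS} columns present"
        )
    if not (has_raw or has_proc):
        raise ValueError(
            f"unrecognised header in {path}: expected raw columns "
            f"{RAW_CURVE_COLUMNS} or processed columns {PROCESSED_CURVE_COLUMNS}"
        )

    if "curve_id" in df.columns:
        groups = [(str(cid), grp) for cid, grp in df.groupby("curve_id", sort=True)]
    else:
        groups = [("curve", df)]

    curves = []
    for cid, grp in groups:
        if has_raw:
            curves.append(
                ForceCurve.from_raw(
                    D=grp["D_um"].to_numpy(float), d=grp["d_um"].to_numpy(float), curve_id=cid
                )
            )
        else:
            curves.append(
                ForceCurve.from_processed(
                    delta=grp["delta_um"].to_numpy(float),
                    F=grp["F_nN"].to_numpy(float),
                    curve_id=cid,
                )
            )
    log.info("read %d force curve(s) from %s (%s dialect)", len(curves), path, "raw" if has_raw else "processed")
    return curves


def write_force_curve(curve: ForceCurve, path: PathLike) -> None:
    """Write one curve in its own dialect (raw or processed)."""
    if curve.is_raw:
        df = pd.DataFrame({"curve_id": curve.curve_id, "D_um": curve.D, "d_um": curve.d})
    else:
        df = pd.DataFrame({"curve_id": curve.curve_id, "delta_um": curve.delta, "F_nN": curve.F})
    df.to_csv(path, index=False)


def read_sweeps(path: PathLike) -> List[RheologySweep]:
    """Read gap sweeps from a long CSV (sample_id, gap_mm, G_prime_Pa)."""
    df = pd.read_csv(path)
    for col in ("gap_mm", "G_prime_Pa"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    if "sample_id" in df.columns:
        groups = [(str(sid), grp) for sid, grp in df.groupby("sample_id", sort=True)]
    else:
        groups = [("sample", df)]
    return [
        RheologySweep(
            gaps=grp["gap_mm"].to_numpy(float),
            G_prime=grp["G_prime_Pa"].to_numpy(float),
            sample_id=sid,
        )
        for sid, grp in groups
    ]


def write_sweep(sweep: RheologySweep, path: PathLike) -> None:
    pd.DataFrame(
        {"sample_id": sweep.sample_id, "gap_mm": sweep.gaps, "G_prime_Pa": sweep.G_prime}
    ).to_csv(path, index=False)


def write_track_metrics(metrics: Iterable[TrackMetrics], path: PathLike) -> None:
    """Per-track metrics CSV (one row per track)."""
    pd.DataFrame([dataclasses.asdict(m) for m in metrics]).to_csv(path, index=False)


def _jsonable(value):
    if isinstance(value, float) and np.isnan(value):
        return None
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def write_cohort_summary(summary: CohortSummary, path: PathLike, **extra) -> None:
    """Cohort summary as JSON (NaNs serialised as null); ``extra`` keys are merged in."""
    payload = {k: _jsonable(v) for k, v in dataclasses.asdict(summary).items()}
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_fit_results(results: Iterable[HertzFitResult], path: PathLike) -> None:
    """Per-curve Hertz fit results as CSV."""
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(path, index=False)
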