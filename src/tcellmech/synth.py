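"""Synthetic-data generators for every stage of the toolkit.

Each generator forward-simulates data with exactly the statistical
structure the corresponding analysis stage assumes, so estimator-recovery
tests (generate → analyse → compare to the generating parameter) exercise
every pipeline without any external data.

* ``simulate_tracks`` — a two-population cohort: arrested cells jitter in
  place (isotropic Gaussian steps), migrating cells follow a persistent
  random walk. Each migrating cell gets its own mean speed drawn from a
  truncated-at-zero Gaussian with the cohort mean and *between-cell* SD;
  individual step speeds fluctuate around the cell mean with a fixed
  coefficient of variation. The between-cell SD is what sets the cohort
  SEM, matching how migration speeds are reported (mean ± SEM over cells).
* ``simulate_indentation`` — noisy Hertz force curves emitted as raw
  cantilever pairs (D = δ + F/k, d = δ), so the raw-conversion step is
  inverted exactly at zero noise. Force noise is multiplicative.
* ``simulate_gap_sweep`` — a saturating G'(gap) loading profile that
  reaches its plateau exactly at the smallest gap, plus additive Gaussian
  noise clipped at zero.

All generators are bit-reproducible under a fixed seed. Named fixtures
(``fixtures.json``) carry the per-condition anchoring values with a
``source`` provenance label on each entry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Any, Dict, List

import numpy as np

from .indentation import ForceCurve, hertz_force
from .rheology import RheologySweep
from .tracks import Track

__all__ = [
    "TrackSimParams",
    "IndentSimParams",
    "SweepSimParams",
    "simulate_tracks",
    "simulate_indentation",
    "simulate_gap_sweep",
    "load_fixtures",
    "list_fixtures",
    "track_params_from_fixture",
    "indent_params_from_fixture",
    "sweep_params_from_fixture",
]

#: Within-cell step-speed coefficient of variation (migrating cells).
STEP_SPEED_CV = 0.25
#: Field of view edge length for initial positions, µm.
FIELD_UM = 200.0


@dataclass(frozen=True)
class TrackSimParams:
    """Two-population cohort simulation parameters.

    Speeds in µm/min; ``migrating_speed_sd`` is the between-cell SD of
    per-cell mean speeds. ``arrested_jitter_sd`` is the per-frame,
    per-axis Gaussian step SD (µm) of arrested cells — small enough that
    a 5-min arrested track stays well below the 10 µm excursion threshold.
    ``persistence`` in [0, 1] sets directional memory: per-step turning
    angles are Gaussian with SD (1 - persistence)·π radians.
    """

    n_cells: int = 100
    frac_arrested: float = 0.0
    migrating_speed_mean: float = 15.5
    migrating_speed_sd: float = 4.0
    arrested_jitter_sd: float = 0.1
    persistence: float = 0.7
    dt: float = 5.0
    duration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (0.0 <= self.frac_arrested <= 1.0):
            raise ValueError("frac_arrested must be in [0, 1]")
        if self.migrating_speed_mean < 0 or self.migrating_speed_sd < 0:
            raise ValueError("speeds must be non-negative")
        if self.arrested_jitter_sd < 0:
            raise ValueError("arrested_jitter_sd must be non-negative")
        if not (0.0 <= self.persistence <= 1.0):
            raise ValueError("persistence must be in [0, 1]")
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")


@dataclass(frozen=True)
class IndentSimParams:
    """Hertz forward-model simulation parameters (lengths µm, E in Pa)."""

    E_true: float = 1720.0
    R: float = 5.7
    nu: float = 0.5
    k: float = 3.0
    delta_max: float = 2.0
    n_points: int = 50
    force_noise_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E_true < 0:
            raise ValueError("E_true must be non-negative")
        for name in ("R", "k", "delta_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.force_noise_cv < 0:
            raise ValueError("force_noise_cv must be non-negative")


@dataclass(frozen=True)
class SweepSimParams:
    """Saturating G'(gap) sweep parameters (gaps mm, moduli Pa)."""

    G_plateau_true: float = 2212.0
    n_gaps: int = 12
    gap_max_mm: float = 1.10
    gap_min_mm: float = 0.90
    loading_shape: float = 3.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G_plateau_true <= 0:
            raise ValueError("G_plateau_true must be positive")
        if self.n_gaps < 1:
            raise ValueError("n_gaps must be >= 1")
        if not (0 < self.gap_min_mm < self.gap_max_mm):
            raise ValueError("need 0 < gap_min_mm < gap_max_mm")
        if self.loading_shape <= 0:
            raise ValueError("loading_shape must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Truncated-at-zero Gaussian draws by rejection (truncation mass is tiny here)."""
    if sd == 0:
        return np.full(size, max(mean, 0.0))
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def simulate_tracks(params: TrackSimParams) -> List[Track]:
    """Generate a cohort of 2D tracks; deterministic under the seed."""
    rng = np.random.default_rng(params.seed)
    n_steps = int(round(params.duration / params.dt))
    times = np.arange(n_steps + 1) * params.dt
    turn_sd = (1.0 - params.persistence) * math.pi

    tracks: List[Track] = []
    for i in range(params.n_cells):
        arrested = rng.random() < params.frac_arrested
        start = rng.uniform(0.0, FIELD_UM, 2)
        if arrested:
            steps = rng.normal(0.0, params.arrested_jitter_sd, (n_steps, 2))
        else:
            cell_mean = _truncated_normal(
                rng, params.migrating_speed_mean, params.migrating_speed_sd, 1
            )[0]
            speeds = _truncated_normal(rng, cell_mean, STEP_SPEED_CV * cell_mean, n_steps)
            lengths = speeds * params.dt / 60.0  # µm/min → µm per frame
            heading = rng.uniform(0.0, 2.0 * math.pi)
            turns = rng.normal(0.0, turn_sd, n_steps)
            headings = heading + np.cumsum(turns)
            steps = lengths[:, None] * np.column_stack(
                [np.cos(headings), np.sin(headings)]
            )
        pos = start + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        tracks.append(
            Track(track_id=f"sim-{i:04d}", times=times, xs=pos[:, 0], ys=pos[:, 1])
        )
    return tracks


def simulate_indentation(params: IndentSimParams) -> ForceCurve:
    """One noisy Hertz force curve as raw cantilever (D, d) pairs.

    δ runs linearly over (0, delta_max]; F = (16/9)√R E δ^{3/2} (1 + ε)
    with ε ~ N(0, force_noise_cv²); D = δ + F/k and d = δ, so the raw
    conversion step recovers (δ, F) exactly.
    """
    rng = np.random.default_rng(params.seed)
    delta = np.linspace(0.0, params.delta_max, params.n_points + 1)[1:]
    F = hertz_force(delta, params.E_true, params.R)
    if params.force_noise_cv > 0:
        F = F * (1.0 + rng.normal(0.0, params.force_noise_cv, params.n_points))
        F = np.clip(F, 0.0, None)
    D = delta + F / params.k
    return ForceCurve.from_raw(D=D, d=delta, curve_id=f"sim-seed{params.seed}")


def simulate_gap_sweep(params: SweepSimParams) -> RheologySweep:
    """One gap sweep, acquired with decreasing gap.

    The noiseless profile is ``plateau · exp(-shape·(gap - gap_min) /
    (gap_max - gap_min))``: monotone increasing as the gap decreases and
    exactly equal to the plateau at the smallest gap, so at zero noise
    the plateau-as-maximum estimator returns the generating value exactly.
    """
    rng = np.random.default_rng(params.seed)
    gaps = np.linspace(params.gap_max_mm, params.gap_min_mm, params.n_gaps)
    span = params.gap_max_mm - params.gap_min_mm
    profile = params.G_plateau_true * np.exp(
        -params.loading_shape * (gaps - params.gap_min_mm) / span
    )
    if params.noise_sd > 0:
        profile = profile + rng.normal(0.0, params.noise_sd, params.n_gaps)
    profile = np.clip(profile, 0.0, None)
    return RheologySweep(gaps=gaps, G_prime=profile, sample_id=f"sim-seed{params.seed}")


# ---------------------------------------------------------------------------
# Named fixtures

def load_fixtures() -> Dict[str, Any]:
    """The shipped fixture table (per-condition anchoring parameters)."""
    text = resources.files("tcellmech").joinpath("fixtures.json").read_text()
    return json.loads(text)


def list_fixtures() -> Dict[str, List[str]]:
    """Fixture names by category (tracks / indentation / rheology / gels)."""
    fx = load_fixtures()
    return {k: sorted(v) for k, v in fx.items() if not k.startswith("_")}


def track_params_from_fixture(
    name: str, n_cells: int = 100, seed: int = 0, **overrides: Any
) -> TrackSimParams:
    """TrackSimParams for a named migration fixture (e.g. ``icam-100kPa``)."""
    entry = _fixture_entry("tracks", name)
    params = TrackSimParams(
        n_cells=n_cells,
        frac_arrested=entry["frac_arrested"],
        migrating_speed_mean=entry["migrating_speed_mean"],
        migrating_speed_sd=entry["migrating_speed_sd"],
        seed=seed,
    )
    return replace(params, **overrides) if overrides else params


def indent_params_from_fixture(
    name: str, seed: int = 0, **overrides: Any
) -> IndentSimParams:
    """IndentSimParams for a named stiffness fixture (e.g. ``hela-28kPa``)."""
    entry = _fixture_entry("indentation", name)
    params = IndentSimParams(E_true=entry["E_true_pa"], seed=seed)
    return replace(params, **overrides) if overrides else params


def sweep_params_from_fixture(name: str, seed: int = 0, **overrides: Any) -> SweepSimParams:
    """SweepSimParams for a named rheology fixture (e.g. ``pa-5pct-sweep``)."""
    entry = _fixture_entry("rheology", name)
    params = SweepSimParams(
        G_plateau_true=entry["G_plateau_true_pa"],
        noise_sd=entry.get("noise_sd_pa", 20.0),
        seed=seed,
    )
    return replace(params, **overrides) if overrides else params


def _fixture_entry(category: str, name: str) -> Dict[str, Any]:
    fx = load_fixtures()
    try:
        return fx[category][name]
    except KeyError:
        known = ", ".join(sorted(fx.get(category, {})))
        raise KeyError(f"unknown {category} fixture {name!r}; known: {known}") from None
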