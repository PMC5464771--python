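"""Parallel-plate shear rheometry of hydrogels: plateau G' and Young's modulus.

Gel discs are compressed between the plates of an oscillatory shear
rheometer while the gap is decreased; the storage modulus G' rises as the
sample is progressively loaded and saturates once full contact is reached.
The characteristic shear modulus of a sample is taken as the *maximum* of
G' over the gap sweep — deliberately the raw maximum, with no smoothing or
plateau-detection heuristic. The tensile (Young's) modulus follows from
linear elasticity as

    E = 2 (1 + ν) G'

with ν = 0.45 for polyacrylamide, i.e. a conversion factor of exactly 2.9.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "RheologySweep",
    "GelElasticity",
    "plateau_shear_modulus",
    "shear_to_young",
    "gel_elasticity",
    "summarize_moduli",
    "DEFAULT_POISSON_GEL",
]

#: Poisson ratio assumed for polyacrylamide.
DEFAULT_POISSON_GEL = 0.45


@dataclass(frozen=True)
class RheologySweep:
    """One gap sweep: (gap, G') pairs at fixed strain and frequency.

    ``gaps`` in mm (monotone, normally decreasing as acquired), ``G_prime``
    in Pa. Strain (%) and frequency (rad/s) are metadata.
    """

    gaps: np.ndarray
    G_prime: np.ndarray
    sample_id: str = "sample"
    strain_pct: float = 5.0
    frequency_rad_s: float = 1.0

    def __post_init__(self) -> None:
        gaps = np.asarray(self.gaps, dtype=float)
        gp = np.asarray(self.G_prime, dtype=float)
        if len(gaps) != len(gp):
            raise ValueError("gaps and G_prime must have the same length")
        if len(gaps) < 1:
            raise ValueError("empty sweep")
        if np.any(gp < 0):
            raise ValueError("G_prime values must be non-negative")
        diffs = np.diff(gaps)
        if len(diffs) and not (np.all(diffs >= 0) or np.all(diffs <= 0)):
            raise ValueError("gaps must be monotone")
        object.__setattr__(self, "gaps", gaps)
        object.__setattr__(self, "G_prime", gp)


@dataclass(frozen=True)
class GelElasticity:
    """Plateau shear modulus and the derived Young's modulus of one sample."""

    sample_id: str
    G_plateau: float  # Pa
    nu: float
    E: float  # Pa = 2 (1 + nu) G_plateau


def plateau_shear_modulus(sweep: RheologySweep) -> float:
    """Characteristic G' of a sweep: the maximum over all gaps, in Pa."""
    return float(np.max(sweep.G_prime))


def shear_to_young(G_plateau: float, nu: float = DEFAULT_POISSON_GEL) -> float:
    """Young's modulus E = 2 (1 + ν) G' in Pa (E = 3G' at ν = 0.5)."""
    if G_plateau < 0:
        raise ValueError("G_plateau must be non-negative")
    if not (-1.0 < nu <= 0.5):
        raise ValueError(f"Poisson ratio {nu} outside (-1, 0.5]")
    return 2.0 * (1.0 + nu) * G_plateau


def gel_elasticity(sweep: RheologySweep, nu: float = DEFAULT_POISSON_GEL) -> GelElasticity:
    """Plateau extraction followed by the shear-to-Young conversion."""
    G = plateau_shear_modulus(sweep)
    return GelElasticity(sample_id=sweep.sample_id, G_plateau=G, nu=nu, E=shear_to_young(G, nu))


def summarize_moduli(
    sweeps: Iterable[RheologySweep], nu: float = DEFAULT_POISSON_GEL
) -> pd.DataFrame:
    """Per-sample moduli plus cohort mean/SD, converting per sample.

    Each sample is converted to E before averaging. By linearity the mean
    E equals 2(1+ν) times the mean G'; the standard deviations differ by
    the same factor, so both are reported.
    """
    rows = [gel_elasticity(s, nu) for s in sweeps]
    if not rows:
        raise ValueError("no sweeps given")
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "G_plateau_Pa": [r.G_plateau for r in rows],
            "E_Pa": [r.E for r in rows],
        }
    )
    df.attrs["nu"] = nu
    df.attrs["G_mean_Pa"] = float(df["G_plateau_Pa"].mean())
    df.attrs["G_sd_Pa"] = float(df["G_plateau_Pa"].std(ddof=1)) if len(df) > 1 else float("nan")
    df.attrs["E_mean_Pa"] = float(df["E_Pa"].mean())
    df.attrs["E_sd_Pa"] = float(df["E_Pa"].std(ddof=1)) if len(df) > 1 else float("nan")
    return df
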