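"""Hertz-model stiffness fitting from cantilever micro-indentation.

A calibrated glass cantilever (spring constant ``k``, spherical tip of
radius ``R``) indents a cell sitting on a rigid support. Lowering the
cantilever base by ``D`` produces a tip displacement ``d < D``; the
deflection ``D - d`` gives the elastic force ``F = k (D - d)`` and the
tip displacement is identified with the indentation depth ``δ = d``.

For a spherical probe on an elastic half-space (Hertz contact),

    F = (4/3) √R · E* · δ^{3/2},      1/E* = (1-ν_cell²)/E_cell + (1-ν_probe²)/E_probe,

and since glass is ~10^6 times stiffer than a cell the rigid-probe limit
``E* = E_cell / (1-ν_cell²)`` applies; with ν_cell = 0.5 this reduces to

    F = (16/9) √R · E_cell · δ^{3/2}.

The model is linear in ``E_cell``, so the least-squares fit is the
closed-form slope of F against (16/9)√R·δ^{3/2} — deterministic and
exact, with no iterative optimisation. Units: forces in nN and lengths
in µm make the slope come out in nN/µm² = kPa; results are reported in Pa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ProbeSpec",
    "ForceCurve",
    "HertzFitResult",
    "hertz_force",
    "raw_to_force_indentation",
    "fit_hertz",
    "reduced_modulus",
]

log = logging.getLogger(__name__)

#: Geometric prefactor of the incompressible (ν=0.5) spherical Hertz model.
HERTZ_PREFACTOR = 16.0 / 9.0


@dataclass(frozen=True)
class ProbeSpec:
    """Cantilever probe: stiffness k (nN/µm), spherical tip radius R (µm).

    ``E_probe`` (Pa) defaults to infinity (rigid probe); ``nu_probe`` is
    only used when ``E_probe`` is finite.
    """

    k: float
    R: float
    E_probe: float = math.inf
    nu_probe: float = 0.2

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("cantilever stiffness k must be positive")
        if self.R <= 0:
            raise ValueError("tip radius R must be positive")


@dataclass(frozen=True)
class ForceCurve:
    """One indentation curve, either raw (D, d) or processed (δ, F).

    Raw curves hold the cantilever base displacement ``D`` and tip
    displacement ``d`` (both µm, deflection D - d >= 0); processed curves
    hold indentation depth ``delta`` (µm) and force ``F`` (nN). Curves are
    assumed pre-zeroed at the contact point (D = d = 0 at contact).
    """

    curve_id: str = "curve"
    D: Optional[np.ndarray] = None
    d: Optional[np.ndarray] = None
    delta: Optional[np.ndarray] = None
    F: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        raw = self.D is not None or self.d is not None
        proc = self.delta is not None or self.F is not None
        if raw and proc:
            raise ValueError("curve must be raw (D, d) or processed (delta, F), not both")
        if raw:
            if self.D is None or self.d is None:
                raise ValueError("raw curve needs both D and d")
            D = np.asarray(self.D, dtype=float)
            d = np.asarray(self.d, dtype=float)
            if D.shape != d.shape:
                raise ValueError("D and d must have the same length")
            object.__setattr__(self, "D", D)
            object.__setattr__(self, "d", d)
        elif proc:
            if self.delta is None or self.F is None:
                raise ValueError("processed curve needs both delta and F")
            delta = np.asarray(self.delta, dtype=float)
            F = np.asarray(self.F, dtype=float)
            if delta.shape != F.shape:
                raise ValueError("delta and F must have the same length")
            object.__setattr__(self, "delta", delta)
            object.__setattr__(self, "F", F)
        else:
            raise ValueError("curve needs either (D, d) or (delta, F) data")

    @property
    def is_raw(self) -> bool:
        return self.D is not None

    @property
    def n_points(self) -> int:
        arr = self.D if self.is_raw else self.delta
        return len(arr)  # type: ignore[arg-type]

    @classmethod
    def from_raw(cls, D, d, curve_id: str = "curve") -> "ForceCurve":
        return cls(curve_id=curve_id, D=np.asarray(D, float), d=np.asarray(d, float))

    @classmethod
    def from_processed(cls, delta, F, curve_id: str = "curve") -> "ForceCurve":
        return cls(curve_id=curve_id, delta=np.asarray(delta, float), F=np.asarray(F, float))


@dataclass(frozen=True)
class HertzFitResult:
    """Fitted cell Young's modulus and bookkeeping for one curve."""

    curve_id: str
    E_cell: float  # Pa
    nu_cell: float
    E_star: float  # Pa, reduced modulus
    residual_rms: float  # nN
    n_points: int
    clamped: bool = False  # True when a negative slope was clamped to 0


def hertz_force(delta_um, E_pa: float, R_um: float) -> np.ndarray:
    """Forward model: force (nN) at indentation depth δ (µm) for ν=0.5.

    ``F = (16/9) √R E δ^{3/2}`` with E converted from Pa to nN/µm² (= kPa).
    """
    delta = np.asarray(delta_um, dtype=float)
    return HERTZ_PREFACTOR * math.sqrt(R_um) * (E_pa / 1000.0) * delta**1.5


def raw_to_force_indentation(
    curve: ForceCurve,
    probe: ProbeSpec,
    deflection_tol: float = 1e-9,
) -> ForceCurve:
    """Convert raw (D, d) pairs to processed (δ, F) pairs.

    ``F = k (D - d)`` and ``δ = d``. Deflections more negative than
    ``-deflection_tol`` (µm) raise; smaller negative values, attributable
    to noise, are clipped to zero force.
    """
    if not curve.is_raw:
        raise ValueError(f"curve {curve.curve_id!r} is already processed")
    deflection = curve.D - curve.d
    if np.any(deflection < -deflection_tol):
        raise ValueError(
            f"curve {curve.curve_id!r}: negative deflection (d > D); "
            "check the raw columns or the contact-point zeroing"
        )
    F = probe.k * np.clip(deflection, 0.0, None)
    return ForceCurve.from_processed(curve.d, F, curve_id=curve.curve_id)


def fit_hertz(
    curve: ForceCurve,
    probe: ProbeSpec,
    nu_cell: float = 0.5,
    delta_max: Optional[float] = None,
    contact_offset: float = 0.0,
) -> HertzFitResult:
    """Fit the ν=0.5 spherical Hertz model and return the cell modulus.

    Minimises the sum of squared force residuals of
    ``F - (16/9)√R E δ^{3/2}``; being linear in E the optimum is the
    closed-form slope ``Σ x F / Σ x²`` with ``x = (16/9)√R δ^{3/2}``,
    constrained to E >= 0 (a negative slope is clamped with a warning).

    ``contact_offset`` (µm) is subtracted from δ before fitting (manual
    contact-point correction); points with δ <= 0 after offsetting, or
    beyond ``delta_max``, are dropped and logged.
    """
    if curve.is_raw:
        curve = raw_to_force_indentation(curve, probe)
    _validate_nu(nu_cell)

    delta = curve.delta - contact_offset
    F = curve.F
    keep = delta > 0
    if delta_max is not None:
        keep &= delta <= delta_max
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info(
            "curve %r: dropped %d of %d points (delta <= 0 or beyond window)",
            curve.curve_id,
            n_dropped,
            curve.n_points,
        )
    delta, F = delta[keep], F[keep]
    if len(delta) == 0:
        raise ValueError(f"curve {curve.curve_id!r}: no indentation (all delta <= 0)")

    x = HERTZ_PREFACTOR * math.sqrt(probe.R) * delta**1.5  # regressor, µm²-scaled
    slope = float(x @ F / (x @ x))  # nN/µm² = kPa
    clamped = False
    if slope < 0:
        log.warning(
            "curve %r: negative fitted slope (%.3g kPa) clamped to 0", curve.curve_id, slope
        )
        slope = 0.0
        clamped = True
    E_cell = slope * 1000.0  # Pa
    residuals = F - slope * x
    return HertzFitResult(
        curve_id=curve.curve_id,
        E_cell=E_cell,
        nu_cell=nu_cell,
        E_star=reduced_modulus(E_cell, nu_cell, probe.E_probe, probe.nu_probe),
        residual_rms=float(np.sqrt(np.mean(residuals**2))),
        n_points=int(len(delta)),
        clamped=clamped,
    )


def _validate_nu(nu: float) -> None:
    if not (-1.0 < nu <= 0.5):
        raise ValueError(f"Poisson ratio {nu} outside (-1, 0.5]")


def reduced_modulus(
    E_cell: float,
    nu_cell: float = 0.5,
    E_probe: float = math.inf,
    nu_probe: float = 0.2,
) -> float:
    """Composite contact modulus E* of the cell-probe pair, in Pa.

    Full two-material formula
    ``1/E* = (1-ν_cell²)/E_cell + (1-ν_probe²)/E_probe``; with a rigid
    probe (E_probe infinite) this reduces to ``E* = E_cell/(1-ν_cell²)``.
    """
    if E_cell < 0:
        raise ValueError("E_cell must be non-negative")
    _validate_nu(nu_cell)
    if E_cell == 0:
        return 0.0
    if math.isinf(E_probe):
        return E_cell / (1.0 - nu_cell**2)
    _validate_nu(nu_probe)
    inv = (1.0 - nu_cell**2) / E_cell + (1.0 - nu_probe**2) / E_probe
    return 1.0 / inv
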