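"""Cantilever-post force transduction and Fung constitutive fitting.

The tensile device suspends a planar tissue strip between two cylindrical
elastomeric cantilever posts.  Post tip deflection ``v`` reports force through
Euler-Bernoulli beam mechanics (``k = 3 E I / L^3``); tip-to-tip separation
``s`` reports the global stretch ratio ``lambda = s / s0``.  Stress-stretch
records are fit to the one-dimensional exponential Fung law

    sigma(eps) = alpha * (exp(beta * eps) - 1),      eps = lambda - 1,

whose tangent ``d sigma / d eps = alpha * beta * exp(beta * eps_ref)`` at a
reference strain is reported as the effective tissue modulus.

All quantities are SI (metres, pascals, newtons); stretch and beta are
dimensionless.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    CompressionWarning,
    DataQualityError,
    FitFailureError,
    InvalidGeometryError,
    InvalidSpecimenError,
)

#: Default reference strain for the effective modulus: midpoint of the
#: lambda <= 1.6 loading protocol.
DEFAULT_EPS_REF = 0.3

#: Schema of the mechanical record CSV written by the simulator.
RECORD_COLUMNS = [
    "step",
    "displacement_m",
    "deflection_m",
    "separation_m",
    "stretch",
    "force_N",
]


@dataclass(frozen=True)
class PostGeometry:
    """Cylindrical elastomer cantilever: the force transducer of the device.

    Parameters
    ----------
    diameter, length : float
        Post diameter and free (axial) length in metres.
    elastic_modulus : float
        Young's modulus of the cured elastomer in Pa.
    base_separation : float
        Tip-to-tip post separation at rest, in metres; also the specimen
        rest length in the standard mounting.
    """

    diameter: float
    length: float
    elastic_modulus: float
    base_separation: float = 500e-6

    def __post_init__(self) -> None:
        for name in ("diameter", "length", "elastic_modulus", "base_separation"):
            if not getattr(self, name) > 0:
                raise InvalidGeometryError(f"{name} must be positive, got {getattr(self, name)!r}")

    @property
    def second_moment(self) -> float:
        """Area moment of inertia of the circular cross-section, pi d^4 / 64."""
        return math.pi * self.diameter**4 / 64.0


@dataclass(frozen=True)
class StressStrainCurve:
    """Uniaxial stretch-stress record referred to the undeformed cross-section."""

    stretch: np.ndarray
    stress: np.ndarray
    specimen_width: float
    specimen_thickness: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "stretch", np.asarray(self.stretch, dtype=float))
        object.__setattr__(self, "stress", np.asarray(self.stress, dtype=float))
        if self.stretch.ndim != 1 or self.stress.ndim != 1:
            raise ValueError("stretch and stress must be 1-D")
        if len(self.stretch) != len(self.stress):
            raise ValueError("stretch and stress must have equal length")
        if len(self.stretch) < 3:
            raise ValueError("need at least 3 points")
        if np.any(self.stretch < 1.0):
            raise ValueError("stretch values must be >= 1")
        if np.any(np.diff(self.stretch) <= 0):
            raise ValueError("stretch values must be strictly increasing")
        if not (self.specimen_width > 0 and self.specimen_thickness > 0):
            raise InvalidSpecimenError("specimen dimensions must be positive")

    @property
    def strain(self) -> np.ndarray:
        """Engineering strain eps = lambda - 1."""
        return self.stretch - 1.0


@dataclass(frozen=True)
class FungFit:
    """Result of a least-squares exponential Fung fit."""

    alpha: float
    beta: float
    eff_modulus: float
    residual_norm: float
    r_squared: float
    eps_ref: float = DEFAULT_EPS_REF
    n_obs: int = 0
    strain_measure: str = "engineering"


def post_bending_stiffness(geometry: PostGeometry) -> float:
    """Tip stiffness of a cantilevered circular beam under a point tip load.

    k = 3 E I / L^3 with I = pi d^4 / 64.  Returns N/m.
    """
    return 3.0 * geometry.elastic_modulus * geometry.second_moment / geometry.length**3


def force_from_deflection(deflection: float, stiffness: float) -> float:
    """Tip force F = k * v in newtons.  Sign follows the deflection."""
    if not stiffness > 0:
        raise InvalidGeometryError(f"stiffness must be positive, got {stiffness!r}")
    return stiffness * deflection


def stretch_from_separation(separation: float, rest_separation: float) -> float:
    """Global stretch ratio lambda = s / s0 from tip-to-tip post separation.

    Separations below the rest separation are outside the tensile analysis
    range and emit a :class:`CompressionWarning`.
    """
    if not rest_separation > 0:
        raise InvalidGeometryError("rest separation must be positive")
    if separation < 0:
        raise ValueError("separation cannot be negative")
    lam = separation / rest_separation
    if lam < 1.0:
        warnings.warn(
            f"separation {separation:g} m below rest separation {rest_separation:g} m: "
            "specimen in compression, outside analysis range",
            CompressionWarning,
            stacklevel=2,
        )
    return lam


def nominal_stress(force: float, width: float, thickness: float) -> float:
    """First Piola (nominal) stress: force over the undeformed cross-section."""
    if not (width > 0 and thickness > 0):
        raise InvalidSpecimenError("specimen width and thickness must be positive")
    return force / (width * thickness)


def fung_stress(strain, alpha: float, beta: float):
    """Exponential Fung law sigma = alpha * (exp(beta * eps) - 1)."""
    return alpha * np.expm1(beta * np.asarray(strain, dtype=float))


def _strain(curve: StressStrainCurve, measure: str) -> np.ndarray:
    if measure == "engineering":
        return curve.stretch - 1.0
    if measure == "green":
        return 0.5 * (curve.stretch**2 - 1.0)
    raise ValueError(f"unknown strain measure {measure!r}")


def fit_fung(
    curve: StressStrainCurve,
    eps_ref: float = DEFAULT_EPS_REF,
    strain_measure: str = "engineering",
    max_restarts: int = 6,
) -> FungFit:
    """Least-squares fit of the exponential Fung law to a stress-stretch record.

    Initialization takes beta0 from the log-stress slope over the stiffest
    (upper-strain) third of the curve and alpha0 from matching the peak
    stress; on non-convergence the fit restarts from geometrically perturbed
    beta0 a bounded number of times.

    Raises
    ------
    DataQualityError
        If the stresses are all equal or monotonically decreasing.
    FitFailureError
        If no restart converges; carries solver diagnostics.
    """
    eps = _strain(curve, strain_measure)
    sigma = curve.stress
    if np.ptp(sigma) == 0:
        raise DataQualityError("all stresses equal: nothing to fit")
    if np.all(np.diff(sigma) <= 0) and sigma[-1] < sigma[0]:
        raise DataQualityError("monotone-decreasing stress: not a tensile loading record")

    # beta0 from log-slope of the upper third (positive stresses only)
    upper = eps >= eps[0] + 2.0 / 3.0 * (eps[-1] - eps[0])
    usable = upper & (sigma > 0)
    if usable.sum() >= 2:
        coeffs = np.polyfit(eps[usable], np.log(sigma[usable]), 1)
        beta0 = float(np.clip(coeffs[0], 0.5, 200.0))
    else:
        beta0 = 5.0
    eps_max = float(eps.max())
    sig_max = float(sigma.max())

    def residuals(params):
        a, b = params
        return fung_stress(eps, a, b) - sigma

    diagnostics = {}
    for i, factor in enumerate((1.0, 0.5, 2.0, 0.25, 4.0, 8.0)[: max_restarts + 1]):
        b0 = beta0 * factor
        a0 = sig_max / max(np.expm1(b0 * eps_max), 1e-12)
        sol = least_squares(
            residuals,
            x0=[max(a0, 1e-12), b0],
            bounds=([1e-15, 1e-6], [np.inf, 1e4]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        diagnostics[f"restart_{i}"] = {"beta0": b0, "status": sol.status, "cost": sol.cost}
        if sol.success:
            alpha, beta = map(float, sol.x)
            resid = residuals(sol.x)
            ss_res = float(resid @ resid)
            ss_tot = float(np.sum((sigma - sigma.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            return FungFit(
                alpha=alpha,
                beta=beta,
                eff_modulus=alpha * beta * math.exp(beta * eps_ref),
                residual_norm=math.sqrt(ss_res),
                r_squared=max(min(r2, 1.0), 0.0),
                eps_ref=eps_ref,
                n_obs=len(sigma),
                strain_measure=strain_measure,
            )
    raise FitFailureError("Fung fit did not converge after bounded restarts", diagnostics)


def effective_modulus(fit: FungFit, eps_ref: float = DEFAULT_EPS_REF) -> float:
    """Tangent modulus d sigma / d eps = alpha * beta * exp(beta * eps_ref) in Pa."""
    if eps_ref < 0:
        raise ValueError(f"reference strain must be nonnegative, got {eps_ref!r}")
    return fit.alpha * fit.beta * math.exp(fit.beta * eps_ref)


def stress_strain_from_record(
    record: pd.DataFrame, width: float, thickness: float
) -> StressStrainCurve:
    """Build a stress-stretch curve from a mechanical record table.

    The record follows the simulator CSV schema (``step, displacement_m,
    deflection_m, separation_m, stretch, force_N``); stress is the nominal
    stress of the recorded force.  Steps at or below lambda = 1 carry no
    tensile information and are dropped, keeping the first occurrence of each
    stretch value so the curve is strictly increasing.
    """
    lam = record["stretch"].to_numpy(dtype=float)
    force = record["force_N"].to_numpy(dtype=float)
    keep = lam > 1.0
    lam, force = lam[keep], force[keep]
    lam, idx = np.unique(lam, return_index=True)
    force = force[idx]
    # anchor the curve at the rest state
    lam = np.concatenate([[1.0], lam])
    force = np.concatenate([[0.0], force])
    stress = np.array([nominal_stress(f, width, thickness) for f in force])
    return StressStrainCurve(lam, stress, width, thickness)


def fit_table(fits: dict[str, FungFit]) -> pd.DataFrame:
    """Tidy per-specimen fit table with the documented CSV header."""
    rows = [
        {
            "specimen_id": sid,
            "alpha_Pa": f.alpha,
            "beta": f.beta,
            "eff_modulus_Pa": f.eff_modulus,
            "r2": f.r_squared,
            "eps_ref": f.eps_ref,
        }
        for sid, f in fits.items()
    ]
    return pd.DataFrame(rows, columns=["specimen_id", "alpha_Pa", "beta", "eff_modulus_Pa", "r2", "eps_ref"])
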