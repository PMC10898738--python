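"""Graft and ligament constitutive models.

Grafts are modeled as an uncoupled transversely isotropic Mooney-Rivlin
solid: an isotropic Mooney-Rivlin matrix (coefficients ``c1``, ``c2``)
reinforced by a single fiber family whose Cauchy stress follows the standard
piecewise toe/linear law,

    sigma_f(lam) = 0                                 lam <= 1
    sigma_f(lam) = c3 (exp(c4 (lam - 1)) - 1)        1 < lam < lam_star
    sigma_f(lam) = c5 lam + c6                       lam >= lam_star

with ``c6`` fixed by value continuity at the fiber straightening stretch
``lam_star``.  The incompressible uniaxial closed form used for curve
fitting adds the matrix contribution ``2 (lam^2 - 1/lam)(c1 + c2/lam)``; the
bulk modulus ``K`` drops out of the incompressible limit and is set
separately for near-incompressibility (default ``1000 (c1 + c2)``).

The posterior cruciate ligament is represented as a bundle of nonlinear
tension-only springs (:class:`SpringCurve`).  Residual in-situ ligament
strain is a fiber pre-stretch attached per material (:class:`PreStrainSpec`)
and exported as prestrain element data by the deck writer.

Units: stress MPa, stretch dimensionless, force N, displacement mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, MaterialError

__all__ = [
    "TIMRParams",
    "StressStrainData",
    "SpringCurve",
    "PreStrainSpec",
    "GraftMaterial",
    "fiber_stress",
    "uniaxial_cauchy_stress",
    "fit_uniaxial",
    "spring_force",
    "apply_prestrain",
]


@dataclass(frozen=True)
class TIMRParams:
    """Transversely isotropic Mooney-Rivlin parameter set.

    c1, c2 : matrix Mooney-Rivlin coefficients (MPa)
    c3 : fiber toe-region scaling (MPa)
    c4 : fiber toe exponential rate (dimensionless)
    c5 : fiber linear-region modulus (MPa)
    lambda_star : fiber straightening stretch (> 1)
    K : bulk modulus (MPa); ``None`` -> near-incompressible default
        ``1000 * (c1 + c2)``
    """

    c1: float
    c2: float = 0.0
    c3: float = 0.0
    c4: float = 1.0
    c5: float = 0.0
    lambda_star: float = 1.05
    K: float | None = None

    def __post_init__(self):
        if not self.c1 > 0:
            raise MaterialError("c1 must be > 0")
        if self.c2 < 0 or self.c3 < 0 or self.c5 < 0:
            raise MaterialError("c2, c3, c5 must be >= 0")
        if not self.c4 > 0:
            raise MaterialError("c4 must be > 0")
        if not self.lambda_star > 1:
            raise MaterialError("lambda_star must be > 1")
        if self.K is None:
            object.__setattr__(self, "K", 1000.0 * (self.c1 + self.c2))
        if not self.K > 0:
            raise MaterialError("K must be > 0")

    @property
    def c6(self) -> float:
        """Linear-branch offset fixed by C0 continuity at lambda_star."""
        ls = self.lambda_star
        return self.c3 * (np.exp(self.c4 * (ls - 1.0)) - 1.0) - self.c5 * ls

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3, self.c4, self.c5,
                         self.lambda_star])

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"c1": self.c1, "c2": self.c2, "c3": self.c3,
                       "c4": self.c4, "c5": self.c5,
                       "lambda_star": self.lambda_star, "K": self.K}, fh,
                      indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class StressStrainData:
    """Uniaxial test data: stretch (lambda >= 1, non-decreasing) vs Cauchy
    stress (MPa)."""

    stretches: np.ndarray
    stresses: np.ndarray
    label: str = "tissue"

    def __post_init__(self):
        self.stretches = np.asarray(self.stretches, dtype=float).ravel()
        self.stresses = np.asarray(self.stresses, dtype=float).ravel()
        if self.stretches.shape != self.stresses.shape:
            raise MaterialError("stretch and stress arrays differ in length")
        if np.any(self.stretches < 1.0):
            raise MaterialError("stretches must be >= 1")
        if np.any(np.diff(self.stretches) < 0):
            raise MaterialError("stretches must be non-decreasing")

    def __len__(self):
        return len(self.stretches)

    def to_csv(self, path):
        pd.DataFrame({"stretch": self.stretches,
                      "stress_MPa": self.stresses}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label=None):
        df = pd.read_csv(path)
        return cls(df["stretch"].to_numpy(), df["stress_MPa"].to_numpy(),
                   label=label or "tissue")


@dataclass
class SpringCurve:
    """Force-displacement knots of a tension-only spring bundle.

    Knots are sorted, start at (0, 0), and carry non-negative forces.
    """

    displacements: np.ndarray
    forces: np.ndarray

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=float).ravel()
        self.forces = np.asarray(self.forces, dtype=float).ravel()
        if self.displacements.shape != self.forces.shape or len(self.forces) < 2:
            raise MaterialError("spring curve needs matching arrays of >= 2 knots")
        if np.any(np.diff(self.displacements) <= 0):
            raise MaterialError("spring knots must be strictly sorted")
        if self.displacements[0] != 0.0 or self.forces[0] != 0.0:
            raise MaterialError("first spring knot must be (0, 0)")
        if np.any(self.forces < 0):
            raise MaterialError("spring forces must be >= 0")


@dataclass(frozen=True)
class PreStrainSpec:
    """In-situ fiber stretch applied to a ligament material."""

    stretch: float

    def __post_init__(self):
        if not self.stretch > 0:
            raise MaterialError("prestrain stretch must be > 0")


@dataclass
class GraftMaterial:
    """A named constitutive record as bound into a model spec."""

    name: str
    params: TIMRParams
    prestrain: PreStrainSpec | None = None
    fiber_axis: tuple = (0.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# constitutive evaluation
# ---------------------------------------------------------------------------


def fiber_stress(params: TIMRParams, lam) -> np.ndarray | float:
    """Fiber Cauchy stress (MPa) of the piecewise toe/linear law."""
    lam_arr = np.asarray(lam, dtype=float)
    if not np.all(np.isfinite(lam_arr)):
        raise MaterialError("stretch must be finite")
    if np.any(lam_arr <= 0):
        raise MaterialError("stretch must be positive")
    ls = params.lambda_star
    toe = params.c3 * (np.expm1(params.c4 * (lam_arr - 1.0)))
    lin = params.c5 * lam_arr + params.c6
    out = np.where(lam_arr <= 1.0, 0.0, np.where(lam_arr < ls, toe, lin))
    return out if out.ndim else float(out)


def uniaxial_cauchy_stress(params: TIMRParams, lam) -> np.ndarray | float:
    """Total axial Cauchy stress (MPa) under incompressible uniaxial stretch
    with the fiber family aligned with loading."""
    lam_arr = np.asarray(lam, dtype=float)
    if not np.all(np.isfinite(lam_arr)):
        raise MaterialError("stretch must be finite")
    if np.any(lam_arr <= 0):
        raise MaterialError("stretch must be positive")
    matrix = 2.0 * (lam_arr**2 - 1.0 / lam_arr) * (params.c1 + params.c2 / lam_arr)
    out = matrix + np.asarray(fiber_stress(params, lam_arr))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# curve fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    params: TIMRParams
    residual_norm: float
    n_starts: int


# documented fixed initial guesses (MPa / dimensionless); the fit runs a
# small deterministic multi-start over these and keeps the best residual
_DEFAULT_STARTS = (
    TIMRParams(c1=1.0, c2=0.1, c3=1.0, c4=50.0, c5=300.0, lambda_star=1.05),
    TIMRParams(c1=3.0, c2=0.5, c3=0.3, c4=30.0, c5=600.0, lambda_star=1.03),
    TIMRParams(c1=0.5, c2=0.05, c3=3.0, c4=80.0, c5=150.0, lambda_star=1.07),
    TIMRParams(c1=5.0, c2=1.0, c3=0.5, c4=20.0, c5=1000.0, lambda_star=1.06),
)

_DEFAULT_BOUNDS = (np.array([1e-6, 0.0, 1e-9, 1e-3, 0.0, 1.0 + 1e-6]),
                   np.array([1e3, 1e3, 1e3, 500.0, 1e5, 1.5]))


def fit_uniaxial(data: StressStrainData, initial: TIMRParams | None = None,
                 bounds=None, max_nfev: int = 5000) -> FitResult:
    """Bounded nonlinear least squares of the incompressible uniaxial closed
    form against measured stress-strain data.

    Fits ``(c1, c2, c3, c4, c5, lambda_star)``; ``K`` is not identifiable
    from incompressible uniaxial data and is set to the near-incompressible
    default on the returned parameters.  Deterministic: a fixed documented
    initial guess (or a small fixed multi-start when ``initial`` is None).
    """
    if len(data) < 5:
        raise MaterialError("fitting requires at least 5 data points")
    lo, hi = bounds if bounds is not None else _DEFAULT_BOUNDS
    lo, hi = np.asarray(lo, dtype=float), np.asarray(hi, dtype=float)
    starts = (initial,) if initial is not None else _DEFAULT_STARTS

    lam, sig = data.stretches, data.stresses
    scale = max(np.abs(sig).max(), 1e-12)

    def residual(x):
        p = TIMRParams(c1=x[0], c2=x[1], c3=max(x[2], 0.0), c4=x[3], c5=x[4],
                       lambda_star=x[5])
        return (uniaxial_cauchy_stress(p, lam) - sig) / scale

    best = None
    for start in starts:
        x0 = np.clip(start.as_array(), lo, hi)
        try:
            res = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                                x_scale="jac", xtol=1e-15, ftol=1e-15,
                                gtol=1e-15, max_nfev=max_nfev)
        except Exception:  # a bad start must not kill the multi-start
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("optimizer failed to converge from any start")
    x = best.x
    params = TIMRParams(c1=x[0], c2=x[1], c3=x[2], c4=x[3], c5=x[4],
                        lambda_star=x[5])
    return FitResult(params=params,
                     residual_norm=float(np.linalg.norm(best.fun) * scale),
                     n_starts=len(starts))


# ---------------------------------------------------------------------------
# springs and prestrain
# ---------------------------------------------------------------------------


def spring_force(curve: SpringCurve, displacement) -> np.ndarray | float:
    """Tension-only piecewise-linear spring force (N).

    Zero for non-positive displacement; linear extrapolation of the final
    segment beyond the last knot.
    """
    d = np.asarray(displacement, dtype=float)
    x, f = curve.displacements, curve.forces
    out = np.interp(d, x, f)
    beyond = d > x[-1]
    if np.any(beyond):
        slope = (f[-1] - f[-2]) / (x[-1] - x[-2])
        out = np.where(beyond, f[-1] + slope * (d - x[-1]), out)
    out = np.where(d <= 0, 0.0, out)
    return out if out.ndim else float(out)


def apply_prestrain(spec: PreStrainSpec, material: GraftMaterial) -> GraftMaterial:
    """Attach an in-situ fiber stretch to a material record.

    The deck writer emits the corresponding prestrain element data for every
    domain bound to the material.
    """
    if not isinstance(spec, PreStrainSpec):
        spec = PreStrainSpec(float(spec))
    return replace(material, prestrain=spec)
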