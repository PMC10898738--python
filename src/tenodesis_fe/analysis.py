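"""Outcome metrics for pivot-shift simulations.

Extracts External Tibial Rotation (ETR) and Posterior Tibial Translation
(PTT) of the lateral tibial compartment from rigid-body kinematics,
summarizes them (reduction-phase ranges, mean absolute error against the
native-knee reference), ranks graft-pretension combinations, extracts
peri-tunnel graft stress, and compares combined versus standalone surgery.

Kinematic conventions
---------------------
Poses are the femur expressed in the tibia frame: ``x_tibia = R x_femur +
t``.  The tibial long axis is +z (superior), the flexion axis is x (fixed
in the femur), and the anterior axis is +y, so posterior displacement is
negative y.  ETR is the rotation of the tibia relative to the femur about
the tibial long axis, external positive: with the femur-in-tibia rotation
decomposed as the intrinsic Euler sequence Rx(a) Ry(b) Rz(g) (flexion axis
first, tibia-fixed long axis last -- the joint-coordinate-system order),
ETR = -g in degrees.  PTT is the posterior (-y) displacement of the
femur-projected lateral compartment point (LFP) relative to its position at
the first output step.

Results tables are pandas DataFrames with columns ``aclr_tension``,
``let_tension`` (NaN for standalone rows), ``etr_mae`` (deg), ``ptt_mae``
(mm) and ``max_von_mises`` (MPa), mirroring the published summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import AnalysisError

__all__ = [
    "KinematicsTrace",
    "MetricSeries",
    "RESULTS_COLUMNS",
    "make_results_table",
    "etr_trace",
    "ptt_ltc_trace",
    "range_during_reduction",
    "mae_vs_reference",
    "rank_combinations",
    "peritunnel_max_vonmises",
    "PERITUNNEL_RADIUS_FACTOR",
    "mesh_convergence",
    "ConvergenceResult",
    "stress_reduction_summary",
    "StressReductionSummary",
    "contour_grid",
    "ContourGrid",
    "calibrate_prestrain",
]

RESULTS_COLUMNS = ["aclr_tension", "let_tension", "etr_mae", "ptt_mae",
                   "max_von_mises"]


@dataclass
class KinematicsTrace:
    """Flexion-indexed femur-relative-to-tibia rigid transforms."""

    flexion_deg: np.ndarray
    rotations: np.ndarray     # (n, 3, 3)
    translations: np.ndarray  # (n, 3) mm

    def __post_init__(self):
        self.flexion_deg = np.asarray(self.flexion_deg, dtype=float).ravel()
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations,
                                       dtype=float).reshape(-1, 3)
        n = len(self.flexion_deg)
        if self.rotations.shape != (n, 3, 3) or len(self.translations) != n:
            raise AnalysisError("trace arrays have inconsistent lengths")
        RtR = np.einsum("nij,nik->njk", self.rotations, self.rotations)
        if not np.allclose(RtR, np.eye(3), atol=1e-6):
            raise AnalysisError("rotations are not orthonormal")

    def __len__(self):
        return len(self.flexion_deg)


@dataclass
class MetricSeries:
    """A scalar kinematic metric sampled over knee flexion angles."""

    flexion_deg: np.ndarray
    values: np.ndarray
    name: str = "metric"

    def __post_init__(self):
        self.flexion_deg = np.asarray(self.flexion_deg, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.flexion_deg.shape != self.values.shape:
            raise AnalysisError("metric series length mismatch")

    def to_csv(self, path):
        pd.DataFrame({"flexion_deg": self.flexion_deg,
                      self.name: self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                   name=df.columns[1])


def make_results_table(rows) -> pd.DataFrame:
    """Build a results table from (aclr, let-or-None, etr, ptt, stress) rows."""
    df = pd.DataFrame(rows, columns=RESULTS_COLUMNS).astype(float)
    if (df["aclr_tension"] <= 0).any():
        raise AnalysisError("tensions must be positive")
    if (df["let_tension"].dropna() <= 0).any():
        raise AnalysisError("tensions must be positive")
    if (df[["etr_mae", "ptt_mae", "max_von_mises"]] < 0).any().any():
        raise AnalysisError("errors and stresses must be non-negative")
    return df


# ---------------------------------------------------------------------------
# kinematic metrics
# ---------------------------------------------------------------------------


def etr_trace(trace: KinematicsTrace) -> MetricSeries:
    """External tibial rotation (degrees, external positive) over flexion."""
    # intrinsic XYZ: femur-fixed flexion axis first, tibia-fixed long axis
    # last; the third angle is femoral internal(+)/external(-) rotation
    angles = Rotation.from_matrix(trace.rotations).as_euler("XYZ",
                                                            degrees=True)
    if angles.ndim == 1:
        angles = angles[None, :]
    return MetricSeries(trace.flexion_deg, -angles[:, 2], name="etr_deg")


def ptt_ltc_trace(trace: KinematicsTrace, lfp,
                  anterior_axis=(0.0, 1.0, 0.0)) -> MetricSeries:
    """Posterior translation (mm, posterior positive) of the lateral
    compartment's femoral projection point ``lfp`` (femur frame)."""
    if lfp is None:
        raise AnalysisError("missing LFP point")
    lfp = np.asarray(lfp, dtype=float).reshape(3)
    anterior = np.asarray(anterior_axis, dtype=float).reshape(3)
    pos = np.einsum("nij,j->ni", trace.rotations, lfp) + trace.translations
    anterior_disp = (pos - pos[0]) @ anterior
    return MetricSeries(trace.flexion_deg, -anterior_disp, name="ptt_mm")


def range_during_reduction(series: MetricSeries, window) -> float:
    """max - min of the metric within a flexion window [lo, hi] (inclusive)."""
    lo, hi = window
    mask = (series.flexion_deg >= lo) & (series.flexion_deg <= hi)
    if not np.any(mask):
        raise AnalysisError(f"no samples inside window [{lo}, {hi}]")
    vals = series.values[mask]
    return float(vals.max() - vals.min())


def mae_vs_reference(series: MetricSeries,
                     reference: MetricSeries) -> float:
    """Mean absolute error against the reference series.

    When the two flexion grids differ, the candidate is linearly resampled
    onto the reference grid restricted to the candidate's coverage;
    completely disjoint coverage is an error.
    """
    lo = max(series.flexion_deg.min(), reference.flexion_deg.min())
    hi = min(series.flexion_deg.max(), reference.flexion_deg.max())
    if lo > hi:
        raise AnalysisError("flexion coverage of the two series is disjoint")
    if np.array_equal(series.flexion_deg, reference.flexion_deg):
        return float(np.mean(np.abs(series.values - reference.values)))
    grid = reference.flexion_deg[(reference.flexion_deg >= lo)
                                 & (reference.flexion_deg <= hi)]
    cand = np.interp(grid, series.flexion_deg, series.values)
    ref = np.interp(grid, reference.flexion_deg, reference.values)
    return float(np.mean(np.abs(cand - ref)))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def rank_combinations(table: pd.DataFrame, by: str = "etr") -> pd.DataFrame:
    """Order a results table by ascending ETR or PTT error.

    Ties break on lower ACLR tension, then lower LET tension; the output is
    a permutation of the input rows (index reset).
    """
    if by not in ("etr", "ptt"):
        raise AnalysisError("rank key must be 'etr' or 'ptt'")
    if len(table) == 0:
        raise AnalysisError("cannot rank an empty table")
    col = f"{by}_mae"
    return table.sort_values([col, "aclr_tension", "let_tension"],
                             kind="stable", na_position="last"
                             ).reset_index(drop=True)


PERITUNNEL_RADIUS_FACTOR = 1.5  # default capture radius as x tunnel radius


def peritunnel_max_vonmises(records, insertion_point, radius: float | None
                            = None, tunnel_radius: float | None = None
                            ) -> float:
    """Maximum von Mises stress (MPa) over elements whose centroid lies
    within ``radius`` mm of the femoral tunnel insertion point.

    When ``radius`` is omitted it defaults to
    ``PERITUNNEL_RADIUS_FACTOR * tunnel_radius``.
    """
    if radius is None:
        if tunnel_radius is None:
            raise AnalysisError("give either radius or tunnel_radius")
        radius = PERITUNNEL_RADIUS_FACTOR * tunnel_radius
    records = list(records)
    if not records:
        raise AnalysisError("no stress records")
    pt = np.asarray(insertion_point, dtype=float).reshape(3)
    near = [r.von_mises for r in records
            if np.linalg.norm(np.asarray(r.centroid) - pt) <= radius]
    if not near:
        raise AnalysisError(
            f"no element centroid within {radius} mm of the insertion point")
    return float(max(near))


@dataclass
class StressReductionSummary:
    """Matched-tension graft stress decrease: standalone minus combined."""

    deltas: pd.DataFrame  # columns: aclr_tension, delta_MPa
    max_delta: float
    max_at_tension: float
    mean_delta: float

    def report(self) -> pd.DataFrame:
        """Deltas rounded to 2 decimals for reporting."""
        out = self.deltas.copy()
        out["delta_MPa"] = out["delta_MPa"].round(2)
        return out


def stress_reduction_summary(combined: pd.DataFrame,
                             standalone: pd.DataFrame
                             ) -> StressReductionSummary:
    """Per-ACLR-tension stress decrease of the combined surgery.

    Combined rows are matched to standalone rows at the same ACLR tension;
    where several LET tensions share an ACLR tension, the minimal-LET row is
    used.  delta = standalone stress - combined stress.
    """
    comb = combined.sort_values(["aclr_tension", "let_tension"]) \
        .groupby("aclr_tension", as_index=False).first()
    shared = sorted(set(comb["aclr_tension"])
                    & set(standalone["aclr_tension"]))
    if not shared:
        raise AnalysisError("no shared ACLR tensions between the tables")
    rows = []
    for t in shared:
        sc = float(comb.loc[comb["aclr_tension"] == t,
                            "max_von_mises"].iloc[0])
        ss = float(standalone.loc[standalone["aclr_tension"] == t,
                                  "max_von_mises"].iloc[0])
        rows.append((t, ss - sc))
    deltas = pd.DataFrame(rows, columns=["aclr_tension", "delta_MPa"])
    imax = int(deltas["delta_MPa"].idxmax())
    return StressReductionSummary(
        deltas=deltas,
        max_delta=float(deltas["delta_MPa"].max()),
        max_at_tension=float(deltas["aclr_tension"].iloc[imax]),
        mean_delta=float(deltas["delta_MPa"].mean()))


@dataclass
class ContourGrid:
    """Gridded MAE matrix over (ACLR tension x LET tension) for contouring."""

    aclr_values: np.ndarray
    let_values: np.ndarray
    matrix: np.ndarray         # (n_aclr, n_let)
    min_location: tuple        # (aclr_tension, let_tension)
    min_value: float = field(default=np.nan)

    def to_csv(self, path):
        pd.DataFrame(self.matrix, index=self.aclr_values,
                     columns=self.let_values).to_csv(path)


def contour_grid(results: pd.DataFrame, grid,
                 metric: str = "etr_mae") -> ContourGrid:
    """Arrange per-pair results into a complete (ACLR x LET) matrix.

    ``grid`` is a :class:`~tenodesis_fe.loading_protocols.TensionGrid`;
    every pair must be present or the error names the missing ones.
    """
    if metric not in ("etr_mae", "ptt_mae"):
        raise AnalysisError("metric must be 'etr_mae' or 'ptt_mae'")
    lookup = {(float(r.aclr_tension), float(r.let_tension)):
              float(getattr(r, metric)) for r in results.itertuples()}
    missing = [(a, l) for a in grid.aclr_values for l in grid.let_values
               if (float(a), float(l)) not in lookup]
    if missing:
        raise AnalysisError(f"incomplete grid; missing pairs: {missing}")
    mat = np.array([[lookup[(float(a), float(l))] for l in grid.let_values]
                    for a in grid.aclr_values])
    i, j = np.unravel_index(np.argmin(mat), mat.shape)
    return ContourGrid(aclr_values=np.asarray(grid.aclr_values),
                       let_values=np.asarray(grid.let_values), matrix=mat,
                       min_location=(float(grid.aclr_values[i]),
                                     float(grid.let_values[j])),
                       min_value=float(mat[i, j]))


# ---------------------------------------------------------------------------
# convergence harness
# ---------------------------------------------------------------------------


@dataclass
class ConvergenceResult:
    resolutions: np.ndarray
    values: np.ndarray
    converged_at: float | None  # first resolution meeting the tolerance


def mesh_convergence(evaluate, resolutions, rel_tol: float = 0.01
                     ) -> ConvergenceResult:
    """Refinement study hook: evaluate a scalar quantity at successively
    finer resolutions and report where successive relative change first
    drops below ``rel_tol``.

    ``evaluate`` maps a resolution parameter (e.g. target edge length or
    element count) to a scalar; the tolerance is configuration because no
    universal threshold fits every quantity.
    """
    res = np.asarray(list(resolutions), dtype=float)
    if len(res) < 2:
        raise AnalysisError("need at least 2 resolutions")
    vals = np.array([float(evaluate(r)) for r in res])
    converged = None
    for i in range(1, len(vals)):
        denom = max(abs(vals[i]), 1e-300)
        if abs(vals[i] - vals[i - 1]) / denom < rel_tol:
            converged = float(res[i])
            break
    return ConvergenceResult(resolutions=res, values=vals,
                             converged_at=converged)


# ---------------------------------------------------------------------------
# prestrain calibration
# ---------------------------------------------------------------------------


def calibrate_prestrain(candidates, experimental_points):
    """Pick the ligament fiber pre-stretch whose simulated anterior tibial
    translation best matches the experimental laxity line.

    An ordinary least-squares line is fitted to the experimental (load,
    translation) points; each candidate ``(stretch, abscissae, att_values)``
    is scored by the MSE between its simulated translations and the line
    evaluated at its abscissae.  Returns ``(best_stretch, mse_by_stretch)``;
    ties go to the smaller stretch.
    """
    candidates = list(candidates)
    if not candidates:
        raise AnalysisError("no prestrain candidates")
    pts = np.asarray(experimental_points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise AnalysisError("need at least 2 experimental points")
    slope, intercept = np.polyfit(pts[:, 0], pts[:, 1], 1)
    scores = []
    for stretch, xs, ys in candidates:
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        line = slope * xs + intercept
        scores.append((float(stretch), float(np.mean((ys - line) ** 2))))
    best = min(scores, key=lambda s: (s[1], s[0]))
    return best[0], dict(scores)
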