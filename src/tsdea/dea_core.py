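"""Input-oriented DEA envelopment models (CCR and BCC).

Efficiency of a target DMU is the smallest radial contraction ``theta`` of its
input vector that a convex (VRS/BCC) or conical (CRS/CCR) combination of the
observed DMUs can still dominate:

    min  theta
    s.t. X' lam + S- = theta * x0
         Y' lam - S+ = y0
         sum(lam) = 1        (VRS only)
         lam, S-, S+ >= 0

Slack maximisation is done in a second phase at the optimal ``theta`` (the
numerically robust version of the non-Archimedean epsilon objective, which is
retained as an alternative mode).  Technical efficiency decomposes as
TE = PTE x SE with TE the CRS score, PTE the VRS score and SE = TE/PTE.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel_io import DMUPanel


class ReturnsToScale(str, Enum):
    CRS = "CRS"
    VRS = "VRS"


class Validity(str, Enum):
    VALID = "valid"                # theta = 1, all slacks zero
    WEAKLY_VALID = "weakly_valid"  # theta = 1, some slack nonzero
    INVALID = "invalid"            # theta < 1


class DEASolverError(RuntimeError):
    """The LP solver failed or reported an impossible status."""


@dataclass(frozen=True)
class DEAConfig:
    returns_to_scale: ReturnsToScale = ReturnsToScale.VRS
    slack_phase: str = "two_phase"   # or "epsilon"
    epsilon: float = 1e-6
    lp_tolerance: float = 1e-7
    unity_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.lp_tolerance <= 0 or self.unity_tolerance <= 0:
            raise ValueError("epsilon and tolerances must be positive")
        if self.slack_phase not in ("two_phase", "epsilon"):
            raise ValueError(f"unknown slack_phase {self.slack_phase!r}")


@dataclass
class EfficiencyResult:
    theta: float
    lambdas: np.ndarray        # intensity weight per reference DMU
    input_slacks: np.ndarray   # S-: residual input reductions beyond radial
    output_slacks: np.ndarray  # S+
    validity: Validity
    frontier_inputs: np.ndarray = field(default=None)  # X' lam at the optimum


def _solve_lp(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    return res


def solve_efficiency(
    target: int,
    inputs: np.ndarray,
    outputs: np.ndarray,
    config: DEAConfig | None = None,
) -> EfficiencyResult:
    """Score one DMU against a cross-section of peers.

    ``inputs`` is (n, N) and ``outputs`` (n, M) for the n DMUs of one period;
    ``target`` indexes the DMU being scored.  Returns the radial score, the
    intensity weights, both slack vectors and the validity class.
    """
    if config is None:
        config = DEAConfig()
    X = np.asarray(inputs, float)
    Y = np.asarray(outputs, float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("inputs and outputs must be 2-D with equal row count")
    n, m = X.shape
    s = Y.shape[1]
    if not (0 <= target < n):
        raise IndexError(f"target {target} outside 0..{n - 1}")
    if not (np.all(X > 0) and np.all(Y > 0)):
        raise ValueError("all inputs and outputs must be strictly positive")
    x0, y0 = X[target], Y[target]
    vrs = config.returns_to_scale is ReturnsToScale.VRS

    if config.slack_phase == "epsilon":
        theta, lam, s_minus, s_plus = _solve_epsilon(X, Y, x0, y0, vrs, config)
    else:
        theta = _solve_phase1(X, Y, x0, y0, vrs)
        lam, s_minus, s_plus = _solve_phase2(X, Y, x0, y0, theta, vrs)

    theta = float(min(theta, 1.0))
    if theta <= 0:
        raise DEASolverError(f"non-positive efficiency score {theta}")
    result = EfficiencyResult(
        theta=theta,
        lambdas=lam,
        input_slacks=np.maximum(s_minus, 0.0),
        output_slacks=np.maximum(s_plus, 0.0),
        validity=Validity.INVALID,
        frontier_inputs=X.T @ lam,
    )
    result.validity = classify_validity(result, config)
    return result


def _solve_phase1(X, Y, x0, y0, vrs):
    """min theta over (theta, lam) s.t. X'lam <= theta x0, Y'lam >= y0."""
    n, m = X.shape
    s = Y.shape[1]
    c = np.zeros(1 + n)
    c[0] = 1.0
    # inputs: X' lam - theta x0 <= 0 ; outputs: -Y' lam <= -y0
    A_ub = np.zeros((m + s, 1 + n))
    A_ub[:m, 0] = -x0
    A_ub[:m, 1:] = X.T
    A_ub[m:, 1:] = -Y.T
    b_ub = np.concatenate([np.zeros(m), -y0])
    A_eq = b_eq = None
    if vrs:
        A_eq = np.zeros((1, 1 + n))
        A_eq[0, 1:] = 1.0
        b_eq = [1.0]
    bounds = [(None, None)] + [(0, None)] * n
    res = _solve_lp(c, A_ub, b_ub, A_eq, b_eq, bounds)
    if res.status != 0:
        raise DEASolverError(f"phase-1 LP failed: {res.message}")
    return float(res.x[0])


def _solve_phase2(X, Y, x0, y0, theta, vrs):
    """max e'S- + e'S+ at fixed theta (ties in lam are solver-dependent)."""
    n, m = X.shape
    s = Y.shape[1]
    nv = n + m + s
    c = np.zeros(nv)
    c[n:] = -1.0  # maximize slack sum
    A_eq_rows = []
    b_eq = []
    for i in range(m):
        row = np.zeros(nv)
        row[:n] = X[:, i]
        row[n + i] = 1.0
        A_eq_rows.append(row)
        b_eq.append(theta * x0[i])
    for r in range(s):
        row = np.zeros(nv)
        row[:n] = Y[:, r]
        row[n + m + r] = -1.0
        A_eq_rows.append(row)
        b_eq.append(y0[r])
    if vrs:
        row = np.zeros(nv)
        row[:n] = 1.0
        A_eq_rows.append(row)
        b_eq.append(1.0)
    bounds = [(0, None)] * nv
    # theta sits exactly on the feasibility boundary; relax marginally if the
    # solver declares the restored problem infeasible.
    for bump in (0.0, 1e-10, 1e-8, 1e-7):
        b = list(b_eq)
        for i in range(m):
            b[i] = (theta + bump) * x0[i]
        res = _solve_lp(c, None, None, np.array(A_eq_rows), b, bounds)
        if res.status == 0:
            lam = res.x[:n]
            return lam, res.x[n:n + m], res.x[n + m:]
    raise DEASolverError(f"phase-2 LP failed: {res.message}")


def _solve_epsilon(X, Y, x0, y0, vrs, config):
    """Single LP: min theta - epsilon * (e'S- + e'S+)."""
    n, m = X.shape
    s = Y.shape[1]
    nv = 1 + n + m + s
    c = np.zeros(nv)
    c[0] = 1.0
    c[1 + n:] = -config.epsilon
    A_eq_rows = []
    b_eq = []
    for i in range(m):
        row = np.zeros(nv)
        row[0] = -x0[i]
        row[1:1 + n] = X[:, i]
        row[1 + n + i] = 1.0
        A_eq_rows.append(row)
        b_eq.append(0.0)
    for r in range(s):
        row = np.zeros(nv)
        row[1:1 + n] = Y[:, r]
        row[1 + n + m + r] = -1.0
        A_eq_rows.append(row)
        b_eq.append(y0[r])
    if vrs:
        row = np.zeros(nv)
        row[1:1 + n] = 1.0
        A_eq_rows.append(row)
        b_eq.append(1.0)
    bounds = [(None, None)] + [(0, None)] * (nv - 1)
    res = _solve_lp(c, None, None, np.array(A_eq_rows), b_eq, bounds)
    if res.status != 0:
        raise DEASolverError(f"epsilon LP failed: {res.message}")
    x = res.x
    return float(x[0]), x[1:1 + n], x[1 + n:1 + n + m], x[1 + n + m:]


def classify_validity(result: EfficiencyResult, config: DEAConfig) -> Validity:
    """DEA-validity of a scored DMU: on the frontier with no slack (valid),
    on the frontier with slack (weakly valid), or below it (invalid)."""
    tol = config.unity_tolerance
    on_frontier = result.theta >= 1.0 - tol
    slack_free = (np.all(result.input_slacks <= tol)
                  and np.all(result.output_slacks <= tol))
    if on_frontier and slack_free:
        return Validity.VALID
    if on_frontier:
        return Validity.WEAKLY_VALID
    return Validity.INVALID


def total_slack(result: EfficiencyResult, target_inputs: np.ndarray) -> np.ndarray:
    """Total input reduction to the frontier reference point.

    Per input n:  x_n - sum_j x_nj lam_j  =  (1 - theta) x_n + S-_n  >= 0.
    This combined radial-plus-residual slack is what the stage-2 regression
    explains with the environmental covariates.
    """
    x = np.asarray(target_inputs, float)
    slack = (1.0 - result.theta) * x + result.input_slacks
    if result.frontier_inputs is not None:
        direct = x - result.frontier_inputs
        if np.max(np.abs(direct - slack)) > 1e-6 * max(1.0, float(np.max(x))):
            raise DEASolverError(
                "inconsistent total slack: (1-theta)x + S- disagrees with "
                "x - X'lam beyond tolerance"
            )
    if np.any(slack < -1e-6 * max(1.0, float(np.max(x)))):
        raise DEASolverError("negative total slack beyond tolerance")
    return np.maximum(slack, 0.0)


@dataclass
class DecompositionRow:
    unit: object
    period: object
    te: float    # CRS score
    pte: float   # VRS score
    se: float    # te / pte
    validity: Validity


def decompose(panel_slice: DMUPanel, config: DEAConfig | None = None,
              ) -> list[DecompositionRow]:
    """TE/PTE/SE decomposition for every DMU of a one-period cross-section.

    TE comes from the CRS solve, PTE from the VRS solve and SE = TE/PTE, so
    TE = PTE x SE holds by construction.  The validity class reported is that
    of the VRS (BCC) solve.
    """
    if config is None:
        config = DEAConfig()
    periods = panel_slice.periods
    if len(periods) != 1:
        raise ValueError("decompose expects a single-period slice")
    X, Y = panel_slice.inputs, panel_slice.outputs
    rows = []
    crs_cfg = replace(config, returns_to_scale=ReturnsToScale.CRS)
    vrs_cfg = replace(config, returns_to_scale=ReturnsToScale.VRS)
    for j in range(panel_slice.n_obs):
        try:
            te = solve_efficiency(j, X, Y, crs_cfg).theta
            vrs_res = solve_efficiency(j, X, Y, vrs_cfg)
        except DEASolverError as exc:
            raise DEASolverError(
                f"unit {panel_slice.data[ 'unit' ].iloc[j]!r}: {exc}") from exc
        pte = vrs_res.theta
        rows.append(DecompositionRow(
            unit=panel_slice.data["unit"].iloc[j],
            period=periods[0],
            te=te,
            pte=pte,
            se=te / pte,
            validity=vrs_res.validity,
        ))
    return rows


def decomposition_frame(rows: list[DecompositionRow]) -> pd.DataFrame:
    return pd.DataFrame({
        "unit": [r.unit for r in rows],
        "period": [r.period for r in rows],
        "TE": [r.te for r in rows],
        "PTE": [r.pte for r in rows],
        "SE": [r.se for r in rows],
        "validity": [r.validity.value for r in rows],
    })
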