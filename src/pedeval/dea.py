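"""Input-oriented DEA efficiency programs and the non-radial Malmquist index.

Each decision-making unit (DMU; here a province) converts m inputs into s
outputs in every period.  Efficiency is measured against the constant-
returns frontier spanned by all DMUs of a reference period:

* radial:      min theta  s.t.  sum_j lam_j x_j <= theta x_0,
               sum_j lam_j y_j >= y_0, lam >= 0
* non-radial:  min (sum_i a_i theta_i) / (sum_i a_i) with a separate
               contraction theta_i per input; inputs with a_i = 0 have
               theta_i fixed to 1 and drop out of the objective.

Cross-period scores evaluate one period's observation against another
period's frontier and may exceed 1.  For adjacent periods t, t+1 the
productivity index combines the four within/cross scores as

    PI = [E_tt / E_t1t1] * sqrt( (E_t1t1 * E_t1t) / (E_tt1 * E_tt) )

(algebraically sqrt(E_tt * E_t1t / (E_t1t1 * E_tt1))), computed exactly as
this expression.  Note its orientation: uniform input inflation between the
periods yields PI > 1, so values above one track input expansion relative
to the frontier; ``inverse_index`` is available for the conventional
"improvement > 1" reading.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "PanelDataset",
    "InputWeights",
    "EfficiencyResult",
    "MalmquistRecord",
    "PanelSummary",
    "radial_efficiency",
    "nonradial_efficiency",
    "malmquist",
    "run_panel",
    "summarize",
]

SCORE_TOL = 1e-7  # score comparisons; double-precision LP convention


class PanelError(ValueError):
    """Invalid panel data or request."""


class SolverError(RuntimeError):
    """The LP solver failed to return an optimal solution."""


@dataclass
class PanelDataset:
    """A complete DMU x period x (inputs, outputs) panel, strictly positive.

    ``x`` has shape (n_dmus, n_periods, m) and ``y`` (n_dmus, n_periods, s);
    period order follows ``period_ids``.
    """

    dmu_ids: list[str]
    period_ids: list[str]
    input_names: list[str]
    output_names: list[str]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, t, m, s = len(self.dmu_ids), len(self.period_ids), len(self.input_names), len(self.output_names)
        if self.x.shape != (n, t, m):
            raise PanelError(f"x has shape {self.x.shape}, expected {(n, t, m)}")
        if self.y.shape != (n, t, s):
            raise PanelError(f"y has shape {self.y.shape}, expected {(n, t, s)}")
        if len(set(self.dmu_ids)) != n:
            raise PanelError("duplicate DMU ids")
        if len(set(self.period_ids)) != t:
            raise PanelError("duplicate period ids")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise PanelError("panel contains non-finite values")
        if np.any(self.x <= 0) or np.any(self.y <= 0):
            bad = "inputs" if np.any(self.x <= 0) else "outputs"
            raise PanelError(f"panel {bad} must be strictly positive")

    @property
    def n_dmus(self) -> int:
        return len(self.dmu_ids)

    @property
    def n_periods(self) -> int:
        return len(self.period_ids)

    def dmu_index(self, dmu: str) -> int:
        try:
            return self.dmu_ids.index(dmu)
        except ValueError:
            raise PanelError(f"unknown DMU {dmu!r}") from None

    def period_index(self, period: str) -> int:
        try:
            return self.period_ids.index(period)
        except ValueError:
            raise PanelError(f"unknown period {period!r}") from None


@dataclass
class InputWeights:
    """Per-input preference weights a_i >= 0 for the non-radial program."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.ndim != 1 or np.any(self.alpha < 0):
            raise PanelError("weights must be a nonnegative vector")
        if not np.any(self.alpha > 0):
            raise PanelError("at least one input weight must be positive")

    @classmethod
    def equal(cls, m: int) -> "InputWeights":
        return cls(np.ones(m))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float], input_names: Sequence[str]) -> "InputWeights":
        missing = [n for n in input_names if n not in mapping]
        if missing:
            raise PanelError(f"weights missing for inputs: {missing}")
        return cls(np.array([mapping[n] for n in input_names], dtype=float))


@dataclass
class EfficiencyResult:
    dmu: str
    frontier_period: str
    evaluated_period: str
    mode: str                      # "radial" | "nonradial"
    score: float
    per_input_theta: np.ndarray
    intensities: np.ndarray
    solver_status: str


@dataclass
class MalmquistRecord:
    """The four component efficiencies and the index for one DMU, one pair."""

    dmu: str
    period_t: str
    period_t1: str
    eff_tt: float
    eff_t1t1: float
    eff_t1t: float
    eff_tt1: float
    pi: float

    @staticmethod
    def index_formula(eff_tt: float, eff_t1t1: float, eff_t1t: float, eff_tt1: float) -> float:
        """The productivity index in its stated form (see module docstring)."""
        return (eff_tt / eff_t1t1) * math.sqrt((eff_t1t1 * eff_t1t) / (eff_tt1 * eff_tt))

    @property
    def complete(self) -> bool:
        """False when a component efficiency was infeasible (recorded missing)."""
        return not any(math.isnan(v) for v in
                       (self.eff_tt, self.eff_t1t1, self.eff_t1t, self.eff_tt1))

    @property
    def inverse_index(self) -> float:
        """1/PI: the conventional 'improvement > 1' reading."""
        return 1.0 / self.pi


@dataclass
class PanelSummary:
    """Arithmetic summary of a DMU x period-pair index matrix."""

    dmu_ids: list[str]
    pair_labels: list[str]
    per_dmu_mean: dict[str, float]
    per_pair_mean: dict[str, float]
    per_pair_max: dict[str, float]
    per_pair_min: dict[str, float]
    per_pair_sd: dict[str, float]
    grand_mean: float


def _solve(c, a_ub, b_ub, bounds, context: str, allow_infeasible: bool = False):
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=bounds, method="highs",
                  options={"primal_feasibility_tolerance": 1e-9,
                           "dual_feasibility_tolerance": 1e-9})
    if res.status == 2 and allow_infeasible:
        return res
    if res.status != 0:
        raise SolverError(f"LP failed for {context}: {res.message}")
    return res


def radial_efficiency(panel: PanelDataset, dmu: str, period: str) -> EfficiencyResult:
    """Within-period radial (single contraction factor) efficiency.

    Always feasible for in-sample DMUs (lambda = unit on self); the score
    lies in (0, 1] up to solver tolerance.
    """
    j0 = panel.dmu_index(dmu)
    t = panel.period_index(period)
    xs = panel.x[:, t, :]          # (n, m) frontier inputs
    ys = panel.y[:, t, :]
    x0, y0 = panel.x[j0, t, :], panel.y[j0, t, :]
    n, m = xs.shape
    s = ys.shape[1]
    # variables: [theta, lambda_1..lambda_n]
    c = np.zeros(1 + n)
    c[0] = 1.0
    a_ub = np.zeros((m + s, 1 + n))
    b_ub = np.zeros(m + s)
    a_ub[:m, 0] = -x0
    a_ub[:m, 1:] = xs.T
    a_ub[m:, 1:] = -ys.T
    b_ub[m:] = -y0
    bounds = [(0, None)] * (1 + n)
    res = _solve(c, a_ub, b_ub, bounds, f"radial {dmu}@{period}")
    theta = float(res.x[0])
    return EfficiencyResult(
        dmu=dmu, frontier_period=period, evaluated_period=period, mode="radial",
        score=theta, per_input_theta=np.full(m, theta),
        intensities=res.x[1:], solver_status="optimal",
    )


def nonradial_efficiency(
    panel: PanelDataset,
    dmu: str,
    frontier_period: str,
    evaluated_period: str,
    weights: InputWeights | None = None,
) -> EfficiencyResult:
    """Non-radial efficiency of one observation against one period's frontier.

    The frontier period supplies the reference technology (all DMUs of that
    period); the evaluated period supplies the assessed observation of
    ``dmu``.  Per-input contractions theta_i are free variables, so
    cross-period scores may exceed 1.  Inputs with zero weight have theta_i
    fixed to 1 and are excluded from the objective.
    """
    j0 = panel.dmu_index(dmu)
    r = panel.period_index(frontier_period)
    sidx = panel.period_index(evaluated_period)
    xs = panel.x[:, r, :]
    ys = panel.y[:, r, :]
    x0, y0 = panel.x[j0, sidx, :], panel.y[j0, sidx, :]
    n, m = xs.shape
    s = ys.shape[1]
    w = weights if weights is not None else InputWeights.equal(m)
    if w.alpha.shape[0] != m:
        raise PanelError(f"{w.alpha.shape[0]} weights for {m} inputs")
    active = np.flatnonzero(w.alpha > 0)
    inactive = np.flatnonzero(w.alpha == 0)
    k = active.size
    alpha_sum = float(w.alpha[active].sum())
    # variables: [theta_i for i in active, lambda_1..lambda_n]
    c = np.concatenate([w.alpha[active] / alpha_sum, np.zeros(n)])
    rows = []
    rhs = []
    for pos, i in enumerate(active):        # sum_j lam x_ij - theta_i x_i0 <= 0
        row = np.zeros(k + n)
        row[pos] = -x0[i]
        row[k:] = xs[:, i]
        rows.append(row)
        rhs.append(0.0)
    for i in inactive:                      # theta_i = 1: sum_j lam x_ij <= x_i0
        row = np.zeros(k + n)
        row[k:] = xs[:, i]
        rows.append(row)
        rhs.append(float(x0[i]))
    for rr in range(s):                     # outputs
        row = np.zeros(k + n)
        row[k:] = -ys[:, rr]
        rows.append(row)
        rhs.append(-float(y0[rr]))
    bounds = [(None, None)] * k + [(0, None)] * n
    context = f"nonradial {dmu} frontier={frontier_period} point={evaluated_period}"
    res = _solve(np.asarray(c), np.asarray(rows), np.asarray(rhs), bounds,
                 context, allow_infeasible=True)
    if res.status == 2:
        # only possible with pinned (zero-weight) inputs in cross-period LPs;
        # with all theta_i free, a scaled copy of the unit itself is feasible
        warnings.warn(f"infeasible LP, score recorded as missing: {context}")
        theta = np.full(m, np.nan)
        theta[inactive] = 1.0
        return EfficiencyResult(
            dmu=dmu, frontier_period=frontier_period, evaluated_period=evaluated_period,
            mode="nonradial", score=float("nan"), per_input_theta=theta,
            intensities=np.zeros(n), solver_status="infeasible",
        )
    theta = np.ones(m)
    theta[active] = res.x[:k]
    return EfficiencyResult(
        dmu=dmu, frontier_period=frontier_period, evaluated_period=evaluated_period,
        mode="nonradial", score=float(res.fun), per_input_theta=theta,
        intensities=res.x[k:], solver_status="optimal",
    )


def malmquist(
    panel: PanelDataset, dmu: str, period_t: str, weights: InputWeights | None = None
) -> MalmquistRecord:
    """Productivity index of ``dmu`` between ``period_t`` and the next period."""
    ti = panel.period_index(period_t)
    if ti + 1 >= panel.n_periods:
        raise PanelError(f"period {period_t!r} has no successor in the panel")
    t1 = panel.period_ids[ti + 1]
    e = lambda fr, ev: nonradial_efficiency(panel, dmu, fr, ev, weights).score
    eff_tt = e(period_t, period_t)
    eff_t1t1 = e(t1, t1)
    eff_t1t = e(t1, period_t)
    eff_tt1 = e(period_t, t1)
    parts = (eff_tt, eff_t1t1, eff_t1t, eff_tt1)
    pi = float("nan") if any(math.isnan(v) for v in parts) else \
        MalmquistRecord.index_formula(*parts)
    return MalmquistRecord(
        dmu=dmu, period_t=period_t, period_t1=t1,
        eff_tt=eff_tt, eff_t1t1=eff_t1t1, eff_t1t=eff_t1t, eff_tt1=eff_tt1, pi=pi,
    )


def run_panel(
    panel: PanelDataset, weights: InputWeights | None = None
) -> tuple[list[MalmquistRecord], PanelSummary]:
    """Index records for every DMU and adjacent period pair, plus summary."""
    if panel.n_periods < 2:
        raise PanelError("panel needs at least two periods")
    records = [
        malmquist(panel, dmu, pt, weights)
        for dmu in panel.dmu_ids
        for pt in panel.period_ids[:-1]
    ]
    return records, summarize(records)


def _pair_label(rec: MalmquistRecord) -> str:
    return f"{rec.period_t}=>{rec.period_t1}"


def summarize(records) -> PanelSummary:
    """Summarize an index matrix: per-DMU means; per-pair mean/max/min/sd.

    Accepts either a list of :class:`MalmquistRecord` or a pandas DataFrame
    of indices (DMU rows x period-pair columns).  The standard deviation is
    the sample sd (divisor n-1); the grand mean is the mean of the per-pair
    means, which on a complete panel equals the overall mean.
    """
    import pandas as pd

    if isinstance(records, pd.DataFrame):
        frame = records.astype(float)
    else:
        records = list(records)
        if not records:
            raise PanelError("no records to summarize")
        frame = pd.DataFrame(
            {_pair_label(r): {} for r in records}  # preserve pair order
        )
        for r in records:
            frame.loc[r.dmu, _pair_label(r)] = r.pi
        frame = frame.astype(float)
    if frame.empty:
        raise PanelError("empty index matrix")
    if frame.isna().any().any():
        missing = [(i, c) for i, c in zip(*np.where(frame.isna().values))]
        raise PanelError(f"incomplete index matrix; missing cells at {missing[:5]}")
    return PanelSummary(
        dmu_ids=list(frame.index),
        pair_labels=list(frame.columns),
        per_dmu_mean=frame.mean(axis=1).to_dict(),
        per_pair_mean=frame.mean(axis=0).to_dict(),
        per_pair_max=frame.max(axis=0).to_dict(),
        per_pair_min=frame.min(axis=0).to_dict(),
        per_pair_sd=frame.std(axis=0, ddof=1).to_dict(),
        grand_mean=float(frame.mean(axis=0).mean()),
    )
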