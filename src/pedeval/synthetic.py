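"""Synthetic DMU x period input-output panels with a known frontier.

The generator emulates the statistical shape of a provincial health-system
panel (by default 31 DMUs over 7 annual periods with 9 inputs and 8
outputs) while keeping the production structure analytically known, so
every downstream efficiency and productivity computation has an oracle:

* inputs are drawn once per DMU on the log scale and held constant across
  periods (an optional uniform per-period drift factor rescales them);
* potential output is Cobb-Douglas with constant returns,
  Y*_jt = A_t * prod_i x_i^{beta_i}, with A_{t+1} = A_t * (1 + g_t);
* realized total output contracts by a half-normal inefficiency draw,
  Y_jt = Y*_jt * exp(-u_jt), optionally with multiplicative lognormal
  noise, and is split across the s output indicators by fixed positive
  proportions common to all DMUs.

Because the outputs of all DMUs stay proportional (common split) and the
input bundle of a DMU is the same in both periods of a pair up to a
uniform drift, the four component efficiencies of the productivity index
collapse by LP homogeneity and the index equals

    pi_jt = exp(u_{j,t+1} - u_{j,t}) / (1 + g_t)

exactly, independent of the sample and of the input drift.  With zero
inefficiency this is 1 / (1 + g_t): the closed form behind
:func:`expected_index` and the recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dea import PanelDataset

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate",
    "expected_index",
    "noisy_expected_mean_index",
    "DEFAULT_INPUT_NAMES",
    "DEFAULT_OUTPUT_NAMES",
]

#: Input indicators of the provincial evaluation framework.
DEFAULT_INPUT_NAMES = (
    "health_expenditure",
    "tertiary_pediatric_hospitals",
    "pediatric_hospital_beds",
    "senior_pediatricians",
    "qualified_pediatric_pharmacists",
    "pediatric_medicine_training",
    "pediatrician_patient_load",
    "technical_consultation",
    "public_health_records",
)

#: Output indicators (kept exactly as framed: larger = better in the LP).
DEFAULT_OUTPUT_NAMES = (
    "pediatric_discharges",
    "outpatient_emergency_patients",
    "pediatric_drug_use_scale",
    "class_ab_incidence",
    "class_ab_mortality",
    "family_health_services",
    "effective_child_support",
    "community_medication_guidance",
)


class ConfigError(ValueError):
    """Invalid synthetic-panel configuration."""


@dataclass
class SyntheticConfig:
    """Conditions of the synthetic study panel.

    Defaults mirror the provincial panel shape: 31 DMUs, 7 periods labeled
    2015-2021, 9 inputs, 8 outputs.  ``tech_shift`` g_t is the per-pair
    multiplicative frontier growth (scalar or one value per pair);
    ``sigma_u`` scales the half-normal inefficiency draws;
    ``inefficiency`` chooses per-("period") or fixed per-("dmu") draws;
    ``sigma_v`` adds multiplicative lognormal output noise (default 0:
    the frontier model is exact); ``input_drift`` uniformly rescales all
    inputs per pair (productivity-neutral under constant returns, kept as
    a dial for constructing hand-checkable scenarios).
    """

    n_dmus: int = 31
    n_periods: int = 7
    input_names: Sequence[str] = DEFAULT_INPUT_NAMES
    output_names: Sequence[str] = DEFAULT_OUTPUT_NAMES
    beta: Sequence[float] | None = None          # Cobb-Douglas exponents, sum 1
    tech_shift: float | Sequence[float] = 0.02   # g_t per adjacent pair
    sigma_u: float = 0.1
    inefficiency: str = "period"                 # "period" | "dmu"
    sigma_v: float = 0.0
    input_log_mean: float = 2.0
    input_log_sd: float = 0.5
    input_drift: float | Sequence[float] = 1.0
    output_split: Sequence[float] | None = None  # fixed positive proportions
    first_period: int = 2015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dmus < 1 or self.n_periods < 2:
            raise ConfigError("need n_dmus >= 1 and n_periods >= 2")
        m, s = len(self.input_names), len(self.output_names)
        if m < 1 or s < 1:
            raise ConfigError("need at least one input and one output")
        if self.beta is None:
            self.beta = tuple(1.0 / m for _ in range(m))
        b = np.asarray(self.beta, dtype=float)
        if b.shape != (m,) or np.any(b < 0) or abs(b.sum() - 1.0) > 1e-9:
            raise ConfigError("beta must be m nonnegative exponents summing to 1")
        if self.sigma_u < 0 or self.sigma_v < 0:
            raise ConfigError("noise scales must be nonnegative")
        if self.inefficiency not in ("period", "dmu"):
            raise ConfigError("inefficiency mode must be 'period' or 'dmu'")
        if self.input_log_sd <= 0:
            raise ConfigError("input_log_sd must be positive")
        if self.output_split is None:
            self.output_split = tuple(1.0 / s for _ in range(s))
        p = np.asarray(self.output_split, dtype=float)
        if p.shape != (s,) or np.any(p <= 0):
            raise ConfigError("output_split must be s strictly positive proportions")
        for name, val in (("tech_shift", self.tech_shift), ("input_drift", self.input_drift)):
            arr = np.atleast_1d(np.asarray(val, dtype=float))
            if arr.size not in (1, self.n_periods - 1):
                raise ConfigError(f"{name} must be scalar or one value per period pair")

    def _per_pair(self, val) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(val, dtype=float))
        if arr.size == 1:
            arr = np.repeat(arr, self.n_periods - 1)
        return arr

    @property
    def tech_shifts(self) -> np.ndarray:
        return self._per_pair(self.tech_shift)

    @property
    def input_drifts(self) -> np.ndarray:
        return self._per_pair(self.input_drift)

    @property
    def period_ids(self) -> list[str]:
        return [str(self.first_period + t) for t in range(self.n_periods)]


@dataclass
class SyntheticTruth:
    """Everything needed to predict the DEA results of a generated panel."""

    config: SyntheticConfig
    frontier_levels: np.ndarray     # A_t, shape (n_periods,)
    inefficiency: np.ndarray        # u[j, t] >= 0, shape (n_dmus, n_periods)
    noisy: bool

    def pair_index(self, period_pair: str | int) -> int:
        pairs = [f"{p}=>{q}" for p, q in zip(self.config.period_ids, self.config.period_ids[1:])]
        if isinstance(period_pair, int):
            if not 0 <= period_pair < len(pairs):
                raise ConfigError(f"pair index {period_pair} out of range")
            return period_pair
        if period_pair not in pairs:
            raise ConfigError(f"unknown period pair {period_pair!r}; expected one of {pairs}")
        return pairs.index(period_pair)


def generate(config: SyntheticConfig) -> tuple[PanelDataset, SyntheticTruth]:
    """Draw a strictly positive panel and retain the generating truth.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_dmus, config.n_periods
    m, s = len(config.input_names), len(config.output_names)
    beta = np.asarray(config.beta, dtype=float)
    split = np.asarray(config.output_split, dtype=float)

    base_x = np.exp(rng.normal(config.input_log_mean, config.input_log_sd, size=(n, m)))
    drift_cum = np.concatenate([[1.0], np.cumprod(config.input_drifts)])
    x = base_x[:, None, :] * drift_cum[None, :, None]

    levels = np.concatenate([[1.0], np.cumprod(1.0 + config.tech_shifts)])
    if config.sigma_u == 0:
        u = np.zeros((n, T))
    elif config.inefficiency == "dmu":
        u = np.repeat(np.abs(rng.normal(0.0, config.sigma_u, size=(n, 1))), T, axis=1)
    else:
        u = np.abs(rng.normal(0.0, config.sigma_u, size=(n, T)))

    potential = levels[None, :] * np.prod(x ** beta[None, None, :], axis=2)
    total = potential * np.exp(-u)
    if config.sigma_v > 0:
        total = total * np.exp(rng.normal(0.0, config.sigma_v, size=(n, T)))
    y = total[:, :, None] * split[None, None, :]

    panel = PanelDataset(
        dmu_ids=[f"DMU{j + 1:02d}" for j in range(n)],
        period_ids=config.period_ids,
        input_names=list(config.input_names),
        output_names=list(config.output_names),
        x=x,
        y=y,
    )
    truth = SyntheticTruth(
        config=config, frontier_levels=levels, inefficiency=u,
        noisy=config.sigma_u > 0 or config.sigma_v > 0,
    )
    return panel, truth


def expected_index(truth: SyntheticTruth, period_pair: str | int) -> float:
    """Oracle productivity index for a zero-noise panel: 1 / (1 + g_t).

    Derived by the LP homogeneity argument in the module docstring, not by
    running the DEA engine.  Undefined (raises) for noisy configurations,
    where the index varies by DMU.
    """
    if truth.noisy:
        raise ConfigError("expected_index is defined only for zero-noise configurations")
    k = truth.pair_index(period_pair)
    return 1.0 / (1.0 + float(truth.config.tech_shifts[k]))


def noisy_expected_mean_index(sigma_u: float, g: float) -> float:
    """Large-sample mean index under per-period half-normal inefficiency.

    E[exp(u' - u)] / (1 + g) with u, u' independent half-normal(sigma_u):
    the half-normal moment generating function gives
    E[exp(a U)] = 2 exp(a^2 s^2 / 2) Phi(a s).
    """
    from scipy.stats import norm

    mgf = lambda a: 2.0 * np.exp(a * a * sigma_u * sigma_u / 2.0) * norm.cdf(a * sigma_u)
    return float(mgf(1.0) * mgf(-1.0) / (1.0 + g))
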