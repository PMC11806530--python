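"""Multi-domain-matrix (MDM) importance propagation.

The evaluation framework links four domains: an outcome (the pediatric
medication "direction", PD), five main factors (MF: time, price, effect,
flexibility, safety), three medication-cycle time factors (TF: before /
during / after administration), and seventeen concrete actual factors (AF)
elicited from experts and families.  Importance flows from the outcome
weighting down to the actual factors through chained matrix products:

    M*_AF.AF = sum_{k=1..L} A^k            (transitive influence closure)
    M*_AF.TF = M_AF.TF + M*_AF.AF @ M_AF.TF
    M_AF.MF  = M*_AF.TF @ M_TF.MF
    M_AF.PD  = M_AF.MF @ M_MF.PD           (normalized to a unit-sum vector)

where ``A`` is the AF-to-AF influence matrix (zero diagonal).  The resulting
17-vector of per-factor global weights is the importance profile; the module
also aggregates it by medication stage and by level-1 parent factor, and
ranks factors under a single main-factor goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MF_NAMES",
    "TF_NAMES",
    "STAGES",
    "FactorCode",
    "LabeledMatrix",
    "MdmSpec",
    "ClosureOptions",
    "MdmDerived",
    "GoalRanking",
    "influence_closure",
    "propagate",
    "stage_shares",
    "level1_shares",
    "goal_ranking",
    "rank_agreement",
]

#: Main-factor (MF) columns, in canonical order.
MF_NAMES = ("time", "price", "effect", "flexibility", "safety")

#: Time-factor (TF) rows: medication cycle stages.
TF_NAMES = ("before", "during", "after")

#: Stage of the medication cycle, keyed by the leading letter of a factor id.
STAGES = {"A": "pre", "B": "during", "C": "post"}


class MdmError(ValueError):
    """Invalid MDM input (dimension, label or value problem)."""


@dataclass(frozen=True)
class FactorCode:
    """One evaluation factor code, e.g. ``A-3.2`` (doctor's literacy).

    The leading letter encodes the medication stage (A: pre-medication,
    B: during medication, C: post-medication); level-2 codes carry a
    ``.k`` suffix and name their level-1 parent.
    """

    id: str
    label: str = ""

    def __post_init__(self) -> None:
        letter = self.id[:1]
        if letter not in STAGES:
            raise MdmError(f"factor id {self.id!r} must start with A, B or C")
        rest = self.id[1:]
        if not rest.startswith("-"):
            raise MdmError(f"factor id {self.id!r} is not of the form 'X-j' or 'X-j.k'")

    @property
    def stage(self) -> str:
        """Medication stage: pure function of the leading letter."""
        return STAGES[self.id[0]]

    @property
    def level(self) -> int:
        return 2 if "." in self.id else 1

    @property
    def parent(self) -> str | None:
        """Level-1 parent id for level-2 codes, ``None`` for level-1 codes."""
        if self.level == 1:
            return None
        return self.id.split(".", 1)[0]


@dataclass
class LabeledMatrix:
    """A nonnegative matrix with ordered row and column identifiers."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise MdmError(
                f"value table is {self.values.shape}, expected "
                f"{(len(self.row_ids), len(self.col_ids))}"
            )
        if np.any(self.values < 0):
            raise MdmError("matrix entries must be nonnegative")

    def loc(self, row: str, col: str) -> float:
        return float(self.values[self.row_ids.index(row), self.col_ids.index(col)])

    def row(self, row: str) -> np.ndarray:
        return self.values[self.row_ids.index(row)]

    def col(self, col: str) -> np.ndarray:
        return self.values[:, self.col_ids.index(col)]


def _check_labels(name_a: str, a: Sequence[str], name_b: str, b: Sequence[str]) -> None:
    if list(a) != list(b):
        raise MdmError(f"label mismatch between {name_a} and {name_b}: {list(a)} != {list(b)}")


@dataclass
class MdmSpec:
    """Complete input of the importance-propagation stage.

    Parameters
    ----------
    mf_weights
        Outcome weighting of the five main factors (M_MF.PD); nonnegative,
        unit sum.
    tf_mf
        3x5 Likert-score matrix M_TF.MF (stage x main factor).
    af_tf
        17x3 matrix M_AF.TF (actual factor x stage).
    af_af
        17x17 influence matrix M_AF.AF with zero diagonal.
    factors
        Factor codes; must include every af_tf row id, and the level-1
        parent of every level-2 code present.
    """

    mf_weights: Mapping[str, float]
    tf_mf: LabeledMatrix
    af_tf: LabeledMatrix
    af_af: LabeledMatrix
    factors: list[FactorCode] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.array([self.mf_weights[m] for m in self.tf_mf.col_ids], dtype=float)
        if np.any(w < 0):
            raise MdmError("mf_weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise MdmError(f"mf_weights must sum to 1, got {w.sum()!r}")
        if np.any(self.tf_mf.values > 9.0):
            raise MdmError("tf_mf Likert scores must lie in [0, 9]")
        if self.af_af.row_ids != self.af_af.col_ids:
            raise MdmError("af_af must be square with identical row/col labels")
        if np.any(np.abs(np.diag(self.af_af.values)) > 0):
            raise MdmError("af_af diagonal must be zero (no self-influence)")
        _check_labels("af_tf rows", self.af_tf.row_ids, "af_af rows", self.af_af.row_ids)
        _check_labels("af_tf cols", self.af_tf.col_ids, "tf_mf rows", self.tf_mf.row_ids)
        known = {f.id for f in self.factors}
        if self.factors:
            missing = [a for a in self.af_tf.row_ids if a not in known]
            if missing:
                raise MdmError(f"factor codes missing for af rows: {missing}")
            for f in self.factors:
                if f.level == 2 and f.parent not in known:
                    raise MdmError(f"level-2 factor {f.id} has no parent {f.parent} in factor set")

    @property
    def mf_weight_vector(self) -> np.ndarray:
        return np.array([self.mf_weights[m] for m in self.tf_mf.col_ids], dtype=float)

    def factor_map(self) -> dict[str, FactorCode]:
        return {f.id: f for f in self.factors}


@dataclass(frozen=True)
class ClosureOptions:
    """Settings for the transitive-influence series.

    max_len is the longest influence-path length summed; tol stops the
    series earlier once the max-norm of the k-th power term falls below it.
    normalize="column" rescales each nonzero column of the influence matrix
    to unit sum before the series (the raw elicited strengths, up to 2.0,
    make the unnormalized series diverge); "none" uses the matrix as given.
    """

    max_len: int = 3
    tol: float = 1e-6
    normalize: str = "column"

    def __post_init__(self) -> None:
        if self.max_len < 1:
            raise MdmError("max_len must be >= 1")
        if self.tol <= 0:
            raise MdmError("tol must be positive")
        if self.normalize not in ("none", "column"):
            raise MdmError(f"unknown normalize mode {self.normalize!r}")


def _column_normalize(a: np.ndarray) -> np.ndarray:
    sums = a.sum(axis=0)
    out = a.copy()
    nz = sums > 0
    out[:, nz] = out[:, nz] / sums[nz]
    return out


def influence_closure(
    af_af: LabeledMatrix,
    max_len: int = 3,
    tol: float = 1e-6,
    normalize: str = "none",
) -> tuple[LabeledMatrix, dict]:
    """Transitive influence closure: the matrix-power series sum_{k=1..L} A^k.

    The series is truncated at ``max_len`` or earlier once the max-norm of
    the k-th power term drops below ``tol``.  Returns the closure and a
    settings dict recording the length used and whether the series was
    truncated before meeting ``tol``.
    """
    opts = ClosureOptions(max_len=max_len, tol=tol, normalize=normalize)
    if af_af.row_ids != af_af.col_ids:
        raise MdmError("influence matrix must be square with identical labels")
    a = af_af.values
    if np.any(a < 0):
        raise MdmError("influence matrix entries must be nonnegative")
    if opts.normalize == "column":
        a = _column_normalize(a)
    total = np.zeros_like(a)
    term = np.eye(a.shape[0])
    used = 0
    converged = False
    for _ in range(opts.max_len):
        term = term @ a
        used += 1
        total = total + term
        if np.max(np.abs(term)) < opts.tol:
            converged = True
            break
    settings = {
        "max_len": opts.max_len,
        "tol": opts.tol,
        "normalize": opts.normalize,
        "length_used": used,
        "truncated": not converged,
    }
    return LabeledMatrix(list(af_af.row_ids), list(af_af.col_ids), total), settings


@dataclass
class MdmDerived:
    """All quantities derived from an :class:`MdmSpec` by :func:`propagate`."""

    af_af_closure: LabeledMatrix
    af_tf_star: LabeledMatrix
    af_mf: LabeledMatrix
    af_pd: dict[str, float]          # normalized global weights, unit sum
    af_pd_raw: dict[str, float]      # pre-normalization chained product
    stage_shares: dict[str, dict]
    level1_shares: dict[str, dict]
    settings: dict


def propagate(spec: MdmSpec, closure_options: ClosureOptions | None = None) -> MdmDerived:
    """Run the full importance-propagation chain on an MDM specification."""
    opts = closure_options or ClosureOptions()
    closure, settings = influence_closure(
        spec.af_af, max_len=opts.max_len, tol=opts.tol, normalize=opts.normalize
    )
    af_ids = list(spec.af_tf.row_ids)
    tf_ids = list(spec.af_tf.col_ids)
    mf_ids = list(spec.tf_mf.col_ids)

    star = spec.af_tf.values + closure.values @ spec.af_tf.values
    af_tf_star = LabeledMatrix(af_ids, tf_ids, star)
    af_mf = LabeledMatrix(af_ids, mf_ids, star @ spec.tf_mf.values)
    raw = af_mf.values @ spec.mf_weight_vector
    total = raw.sum()
    if total <= 0:
        raise MdmError("propagated global weights sum to zero; cannot normalize")
    pd_vec = raw / total
    af_pd = dict(zip(af_ids, pd_vec))

    factors = spec.factors or [FactorCode(a) for a in af_ids]
    fmap = {f.id: f for f in factors}
    return MdmDerived(
        af_af_closure=closure,
        af_tf_star=af_tf_star,
        af_mf=af_mf,
        af_pd=af_pd,
        af_pd_raw=dict(zip(af_ids, raw)),
        stage_shares=stage_shares(af_pd, factors),
        level1_shares=level1_shares(af_pd, factors),
        settings=settings,
    )


def _lookup_factors(
    af_pd: Mapping[str, float], factors: Iterable[FactorCode]
) -> dict[str, FactorCode]:
    fmap = {f.id: f for f in factors}
    unknown = [a for a in af_pd if a not in fmap]
    if unknown:
        raise MdmError(f"unknown factor ids: {unknown}")
    return fmap

def stage_shares(
    af_pd: Mapping[str, float], factors: Iterable[FactorCode]
) -> dict[str, dict]:
    """Aggregate per-factor weights by medication stage (pre/during/post).

    Returns, per stage, the summed weight of its member factors, the member
    count, and the mean weight.  The input vector is used as given; on a
    normalized weight vector the three sums add to one.
    """
    fmap = _lookup_factors(af_pd, factors)
    out: dict[str, dict] = {s: {"share": 0.0, "count": 0, "mean": 0.0} for s in ("pre", "during", "post")}
    for fid, w in af_pd.items():
        s = fmap[fid].stage
        out[s]["share"] += float(w)
        out[s]["count"] += 1
    for s, rec in out.items():
        rec["mean"] = rec["share"] / rec["count"] if rec["count"] else 0.0
    return out


def level1_shares(
    af_pd: Mapping[str, float], factors: Iterable[FactorCode]
) -> dict[str, dict]:
    """Aggregate level-2 factor weights by their level-1 parent."""
    fmap = _lookup_factors(af_pd, factors)
    out: dict[str, dict] = {}
    for fid, w in af_pd.items():
        parent = fmap[fid].parent
        if parent is None:
            raise MdmError(f"factor {fid} is level-1; level1_shares expects level-2 weights")
        rec = out.setdefault(parent, {"share": 0.0, "count": 0, "mean": 0.0})
        rec["share"] += float(w)
        rec["count"] += 1
    for rec in out.values():
        rec["mean"] = rec["share"] / rec["count"]
    return out


@dataclass
class GoalRanking:
    """Factors ranked under one main-factor goal.

    ``entries`` holds (factor id, raw score, ratio to the reference score),
    sorted by raw score descending with lexicographic id tie-break; the
    reference is the argmax factor (ratio exactly 1).
    """

    goal: str
    reference: str
    entries: list[tuple[str, float, float]]


def goal_ranking(af_mf: LabeledMatrix, goal: str) -> GoalRanking:
    """Rank actual factors by their score in one main-factor column."""
    if goal not in af_mf.col_ids:
        raise MdmError(f"unknown goal {goal!r}; expected one of {af_mf.col_ids}")
    col = af_mf.col(goal)
    order = sorted(range(len(col)), key=lambda i: (-col[i], af_mf.row_ids[i]))
    ref_i = order[0]
    ref_val = float(col[ref_i])
    entries = []
    for i in order:
        ratio = float(col[i]) / ref_val if ref_val > 0 else (1.0 if i == ref_i else 0.0)
        entries.append((af_mf.row_ids[i], float(col[i]), ratio))
    return GoalRanking(goal=goal, reference=af_mf.row_ids[ref_i], entries=entries)


def rank_agreement(
    computed: Mapping[str, float], reference: Mapping[str, float]
) -> float:
    """Spearman rank correlation between two global-weight vectors.

    Diagnostic for comparing an end-to-end propagated weight vector against
    an externally reported one; the elicitation pipeline behind a reported
    vector rarely documents its normalization, so rank agreement, not
    equality, is the meaningful check.
    """
    from scipy.stats import spearmanr

    keys = sorted(computed)
    if sorted(reference) != keys:
        raise MdmError("weight vectors must cover the same factor ids")
    rho, _ = spearmanr([computed[k] for k in keys], [reference[k] for k in keys])
    return float(rho)
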