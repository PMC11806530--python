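# Methods

## Importance propagation (stage 1)

The evaluation framework links four domains: the outcome (PD), five main
factors (MF: time, price, effect, flexibility, safety), three
medication-cycle stages (TF: before, during, after) and seventeen
level-2 actual factors (AF) grouped under seven level-1 codes. Importance
is pushed from the outcome weighting down to the actual factors by the
chained products documented in the README. The assumptions are those of
the classical design-structure-matrix calculus: influence is additive
along paths, multiplicative across steps, and indirect influence is the
matrix-power series of the direct-influence matrix.

**Closure normalization and length.** The elicited influence strengths
run up to 2.0, so the raw power series diverges; the transmitted share of
influence, not its absolute strength, is what should propagate. The
pipeline therefore column-normalizes the influence matrix (each nonzero
column rescaled to unit sum) before the series and truncates at
`max_len = 3` by default (paths of length ≤ 3), with an early stop when
the max-norm of the k-th term falls below `tol = 1e-6`. Both knobs are
exposed (`ClosureOptions`), the settings used are recorded in the result,
and a series truncated before meeting `tol` is flagged rather than
silently accepted. `influence_closure` itself defaults to no
normalization so that small worked examples (nilpotent chains, single
cycles) can be checked against explicit path enumeration.

**Normalization of the global vector.** The chained product is divided by
its sum so the global weights form a probability vector; the
pre-normalization vector is kept (`af_pd_raw`) because monotonicity
statements (raising a stage score never lowers that factor's weight) hold
on the raw scale, where no renormalization couples the factors.

**Aggregations.** `stage_shares` and `level1_shares` sum the weight
vector they are given without renormalizing. This matters for the
packaged reported column, which sums to 1.001 as printed: its
during-stage sum (0.327) and physician-norm sum (0.258) are exact on the
printed values, and renormalizing would destroy that exactness. On a
normalized vector the aggregates sum to one by construction.

**Goal rankings.** For a chosen main factor the AF×MF column is sorted
descending; the argmax factor is the reference with ratio 1 and ties
break lexicographically on factor id so output is deterministic. Ratios
are relative to the maximum, hence always in [0, 1].

**End-to-end reproduction is a diagnostic, not a target.** The published
global column cannot be re-derived exactly from the raw matrices because
the elicitation pipeline's normalization and series length are not
documented; the package instead reports the Spearman rank correlation
between the propagated and reported vectors (0.767 under default
settings on the packaged instance — examples/importance_propagation.py
computes it). Fixture notes record every typographically ambiguous cell
of the packaged instance and how it was resolved, including the exclusion
of level-1 rows/columns from the 17×17 influence matrix.

## DEA–Malmquist (stage 2)

Efficiency is measured against the constant-returns frontier spanned by
all DMUs of a reference period — no convexity constraint on the
intensities, exactly as the programs are framed. Orientation is input
only. The radial program contracts all inputs by a single factor; the
non-radial program gives each input its own contraction `θ_i`, aggregated
by preference weights `α_i` (default: equal). A zero-weight input has
`θ_i` fixed at 1 and is excluded from the objective.

* **Solver.** All programs are solved with HiGHS (scipy `linprog`) at
  primal/dual feasibility 1e-9; score comparisons in tests use 1e-7.
* **Cross-period scores** may exceed 1 (the evaluated point can dominate
  an earlier frontier). With all `θ_i` free the cross-period LP is always
  feasible — a scaled copy of the unit itself satisfies the constraints —
  but pinning a zero-weight input can make it genuinely infeasible (the
  capped input cannot stretch to reach the evaluated output). Such scores
  are recorded as missing with a warning and the affected index record is
  flagged incomplete, rather than being fabricated.
* **Index orientation.** The index is computed in exactly the form
  `PI = sqrt(E^t(t)·E^{t+1}(t)/(E^{t+1}(t+1)·E^t(t+1)))`. Under this form
  uniform input doubling between periods yields PI = 2 — input expansion,
  conventionally a productivity *decline*, scores above one. The package
  reproduces the formula as given and exposes `inverse_index` (and the
  CLI flag `--report-inverse`) for the conventional reading instead of
  silently flipping it.
* **Outputs as framed.** The indicator framework lists disease incidence
  and mortality among outputs; they are treated exactly as outputs
  (larger = better in the LP). No bad-output transformation is applied —
  users who want one should preprocess.
* **Strict positivity.** Panels are validated to be complete and strictly
  positive at load; an optional epsilon replacement
  (`epsilon × positive column mean`) exists for user data with stray
  zeros, off by default.
* **Summaries.** Per-DMU means, per-pair mean/max/min and *sample*
  standard deviation (divisor n−1); the grand mean is the mean of per-pair
  means, which equals the overall mean on complete panels. Report tables
  render at 4 decimals, the conventional printing for these indices.

Returns-to-scale toggles, output orientation, Malmquist decomposition
(efficiency-change × technical-change), bootstrap intervals and
slack-based measures are out of scope.

## Synthetic panels

The generator produces panels whose DEA results are analytically known,
so recovery tests have independent oracles:

* inputs: lognormal, drawn once per DMU and held constant across periods
  (`input_log_mean = 2.0`, `input_log_sd = 0.5`); an optional uniform
  per-pair drift factor rescales them;
* frontier: Cobb–Douglas with constant returns, equal exponents by
  default, level `A_{t+1} = A_t(1+g_t)` with `g_t = 0.02` by default;
* inefficiency: half-normal with scale `sigma_u = 0.1`, drawn per
  DMU-period (or fixed per DMU); realized total output is
  `Y = A_t · Π x_i^{β_i} · exp(−u)`;
* outputs: the total is split across the output indicators by fixed
  positive proportions common to all DMUs; optional multiplicative
  lognormal noise `sigma_v` (default 0).

Defaults mirror the provincial panel shape (31 DMUs × 7 periods labeled
2015–2021, 9 inputs, 8 outputs named after the indicator framework).

**Why the oracle is exact.** Because the output split is common to all
DMUs, the s outputs are globally proportional and the output constraints
collapse to one; the LP value is then linear in the evaluated unit's
total output and inversely homogeneous in the frontier's output scale.
With inputs fixed per DMU (drift is a uniform column rescaling, which
CRS ignores), the four component efficiencies of the pair (t, t+1)
cancel to

    pi_j = exp(u_{j,t+1} − u_{j,t}) / (1 + g_t)

for every DMU at any sample size. Zero noise gives `pi = 1/(1+g_t)`
(`expected_index`); with per-period half-normal draws the mean index
tends to `E[exp(u'−u)]/(1+g) = 4·exp(σ²)·Φ(σ)·Φ(−σ)/(1+g)`
(`noisy_expected_mean_index`, from the half-normal moment generating
function). The recovery tests run the full LP engine and compare against
these closed forms: exactly (1e-6) for zero noise, and at 200 DMUs × 20
seeds with tolerance 0.006 ≈ 4 Monte-Carlo standard errors for the noisy
mean. The noisy run uses 2 periods and 3 inputs / 2 outputs — the
identity above is sample-size-free, so the smaller panel changes nothing
but the LP count.

**What the generator does not emulate.** Real provincial indicators are
serially correlated, spatially dependent, measured with heterogeneous
units and not generated by a common Cobb–Douglas frontier with a shared
output mix. Passing recovery tests therefore demonstrates the
correctness of the LP engine and index arithmetic under known
conditions, not that real panels satisfy those conditions.

## Degenerate inputs and tie-breaks

Non-square or negative matrices, nonzero influence diagonals, weight
vectors off unit sum, incomplete or non-positive panels, and unknown
factor/goal/DMU/period/fixture names all raise typed errors naming the
offense. Ranking ties break lexicographically; a goal column that is all
zero ranks its lexicographically first factor as reference with ratio 1
and the rest 0. Fixture-level ambiguities are documented in the fixture
files themselves, not patched in code.
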