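# pedeval

Pediatric-medication evaluation analytics for health-system panels in
resource-constrained settings. The package implements a two-stage pipeline:

1. **Multi-domain-matrix (MDM) importance propagation** — turns elicited
   relationship matrices between an outcome, five main factors (time,
   price, effect, flexibility, safety), three medication-cycle stages
   (before / during / after administration) and seventeen concrete
   evaluation factors into per-factor global importance weights, stage and
   first-level aggregates, and goal-conditional rankings.
2. **Non-radial input-oriented DEA–Malmquist productivity analysis** —
   scores productivity change of decision-making units (DMUs; here
   provinces) over a multi-year input–output panel using per-input
   contraction factors with preference weights.

## The model

**Stage 1.** Given the actual-factor influence matrix `A` (zero diagonal),
the stage matrix `M_AF×TF`, the Likert block `M_TF×MF` and the outcome
weights `M_MF×PD`, the pipeline computes

```
M*_AF×AF = Σ_{k=1..L} A_norm^k                 (transitive influence closure)
M*_AF×TF = M_AF×TF + M*_AF×AF · M_AF×TF
M_AF×MF  = M*_AF×TF · M_TF×MF
M_AF×PD  = M_AF×MF · M_MF×PD                   (normalized to unit sum)
```

where `A_norm` is the column-normalized influence matrix and `L` a
configurable series length (default 3).

**Stage 2.** For DMU 0 against the period-`r` frontier, the non-radial
program with input weights `α_i ≥ 0` is

```
min (Σ_i α_i θ_i) / (Σ_i α_i)
s.t. Σ_j λ_j x_ij^r ≤ θ_i x_i0^s   (i = 1..m;  θ_i = 1 fixed when α_i = 0)
     Σ_j λ_j y_rj^r ≥ y_r0^s       (r = 1..s)
     λ_j ≥ 0,  θ_i free
```

under constant returns to scale. With the four within/cross-period scores
`E^a(b)` (frontier period `a`, data period `b`) the productivity index for
the adjacent pair (t, t+1) is

```
PI = [E^t(t) / E^{t+1}(t+1)] · sqrt( E^{t+1}(t+1)·E^{t+1}(t) / (E^t(t+1)·E^t(t)) )
   = sqrt( E^t(t)·E^{t+1}(t) / (E^{t+1}(t+1)·E^t(t+1)) )
```

computed exactly in this form. Note the orientation: uniform input
inflation yields PI > 1, so `MalmquistRecord.inverse_index` is provided
for the conventional "improvement > 1" reading (see `docs/methods.md`).

## Worked example

```python
import pedeval as pe

spec = pe.load_fixture("table3_mdm")                 # packaged evaluation instance
weights = pe.load_fixture("table3_global_weights")   # reported global column

shares = pe.stage_shares(weights, spec.factors)
print(shares["during"]["share"])      # 0.327  -> 32.7% of importance sits in-medication
level1 = pe.level1_shares(weights, spec.factors)
print(level1["A-3"]["share"])         # 0.258  -> physician norms carry 25.8%

ranking = pe.goal_ranking(pe.load_fixture("table3_af_mf"), "time")
print(ranking.reference)              # 'A-2.2' (parental cognition)
print(ranking.entries[1])             # ('B-2.2', 0.976, 0.976) -> 97.6% of the reference

matrix = pe.load_fixture("table4_malmquist")         # reported 31x6 index matrix
summary = pe.summarize(matrix)
print(round(summary.per_dmu_mean["Beijing"], 4))     # 1.1150
print(round(summary.grand_mean, 4))                  # 1.0239
```

The `examples/` directory holds runnable narrative scripts:
`importance_propagation.py` (full stage-1 chain plus the Spearman
rank-agreement diagnostic against the reported column, 0.767 under default
settings), `goal_rankings.py` (goal-conditional rankings) and
`malmquist_panel.py` (synthetic 31×7 panel through the DEA stage).

A thin CLI mirrors the library:

```
pedeval simulate --dmus 31 --periods 7 --seed 42 --out panel.csv
pedeval dea malmquist --panel panel.csv --out report.csv
pedeval mdm rank --goal time --out ranking.csv
pedeval fixtures list
```

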