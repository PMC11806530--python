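"""Propagate elicited relationship matrices into per-factor importance weights.

Loads the packaged evaluation instance (five main-factor outcome weights,
stage x main-factor Likert scores, 17 actual factors with their stage and
influence matrices), runs the closure-and-chain propagation, and prints the
stage aggregates and the top factors.
"""

import pedeval as pe

spec = pe.load_fixture("table3_mdm")
reported = pe.load_fixture("table3_global_weights")

derived = pe.propagate(spec)
print("closure settings:", derived.settings)

print("\nStage shares of the reported global column (sum, count, mean):")
for stage, rec in pe.stage_shares(reported, spec.factors).items():
    print(f"  {stage:7s} {rec['share']:.3f}  n={rec['count']}  mean={rec['mean']:.4f}")

print("\nLevel-1 aggregates of the reported column:")
for parent, rec in sorted(pe.level1_shares(reported, spec.factors).items()):
    print(f"  {parent}  {rec['share']:.3f}")

print("\nTop 5 factors by propagated global weight:")
labels = {f.id: f.label for f in spec.factors}
for fid, w in sorted(derived.af_pd.items(), key=lambda kv: -kv[1])[:5]:
    print(f"  {fid:6s} {labels[fid]:28s} {w:.3f}")

rho = pe.rank_agreement(derived.af_pd, reported)
print(f"\nSpearman rank agreement with the reported column: {rho:.3f}")
print("(The propagated scale need not match the reported one -- the elicitation")
print(" pipeline's normalization is not published -- but the ranking should agree.)")
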