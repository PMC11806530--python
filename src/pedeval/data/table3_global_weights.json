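{
 "title": "Reported global-importance column over the 17 level-2 factors",
 "notes": [
  "Values as printed; the column sums to 1.001, and its pre/post stage sums (0.536/0.138) differ by 0.001 from the narrative 53.5%/13.7%. Reported during-stage (0.327) and physician-norm (0.258) aggregates are exact on these values."
 ],
 "weights": {
  "A-1.1": 0.031,
  "A-1.2": 0.045,
  "A-2.1": 0.108,
  "A-2.2": 0.094,
  "A-3.1": 0.093,
  "A-3.2": 0.126,
  "A-3.3": 0.039,
  "B-1.1": 0.053,
  "B-1.2": 0.04,
  "B-2.1": 0.076,
  "B-2.2": 0.08,
  "B-2.3": 0.049,
  "B-2.4": 0.029,
  "C-1.1": 0.043,
  "C-1.2": 0.021,
  "C-2.1": 0.07,
  "C-2.2": 0.004
 }
}
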