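{
 "title": "Reported actual-factor x main-factor score block",
 "notes": [
  "Authoritative for goal-conditional rankings; end-to-end propagation from the raw matrices is not required to reproduce it (the source's normalization and series length are unstated)."
 ],
 "af_mf": {
  "rows": [
   "A-1.1",
   "A-1.2",
   "A-2.1",
   "A-2.2",
   "A-3.1",
   "A-3.2",
   "A-3.3",
   "B-1.1",
   "B-1.2",
   "B-2.1",
   "B-2.2",
   "B-2.3",
   "B-2.4",
   "C-1.1",
   "C-1.2",
   "C-2.1",
   "C-2.2"
  ],
  "cols": [
   "time",
   "price",
   "effect",
   "flexibility",
   "safety"
  ],
  "values": [
   [
    0.07,
    0.343,
    0.262,
    0.067,
    0.176
   ],
   [
    0.116,
    0.514,
    0.335,
    0.111,
    0.27
   ],
   [
    0.308,
    1,
    1,
    0.27,
    0.566
   ],
   [
    1,
    0.714,
    0,
    1.01,
    0.802
   ],
   [
    0.488,
    0.234,
    1.078,
    0.578,
    0.344
   ],
   [
    0.837,
    1.403,
    0.32,
    0.753,
    1
   ],
   [
    0,
    0.935,
    0,
    0,
    0.382
   ],
   [
    0.598,
    0,
    0.335,
    0.469,
    0.305
   ],
   [
    0.498,
    0,
    0.192,
    0.391,
    0.254
   ],
   [
    0.697,
    0,
    0.687,
    0.607,
    0.355
   ],
   [
    0.976,
    0,
    0.393,
    0.85,
    0.498
   ],
   [
    0.558,
    0,
    0.306,
    0.486,
    0.284
   ],
   [
    0.349,
    0.171,
    0,
    0.31,
    0.248
   ],
   [
    0.488,
    0,
    0.225,
    0.688,
    0.249
   ],
   [
    0,
    0.468,
    0,
    0.177,
    0.191
   ],
   [
    0.701,
    0.357,
    0.165,
    1,
    0.504
   ],
   [
    0,
    0,
    0,
    0.449,
    0
   ]
  ]
 }
}
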