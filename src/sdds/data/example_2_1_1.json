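{
 "name": "example_2_1_1",
 "description": "Two-variable Boolean worked example: f1 = x2, f2 = x1 AND NOT x2.",
 "init": "01",
 "variables": [
  {
   "name": "x1",
   "levels": 2
  },
  {
   "name": "x2",
   "levels": 2
  }
 ],
 "rules": {
  "x1": "x2",
  "x2": "min(x1, not(x2))"
 },
 "propensities": {
  "x1": {
   "up": 0.1,
   "down": 0.2
  },
  "x2": {
   "up": 0.5,
   "down": 0.9
  }
 }
}
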