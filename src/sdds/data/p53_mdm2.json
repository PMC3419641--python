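{
 "name": "p53_mdm2",
 "description": "Four-variable p53-Mdm2 damage-response network. Nuclear Mdm2 represses p53; p53 drives cytoplasmic Mdm2, which drives nuclear Mdm2; p53 and DNA damage block basal nuclear Mdm2. Damage decays only through its degradation propensity.",
 "init": "0011",
 "variables": [
  {
   "name": "P",
   "levels": 3
  },
  {
   "name": "Mc",
   "levels": 2
  },
  {
   "name": "Mn",
   "levels": 2
  },
  {
   "name": "Dam",
   "levels": 2
  }
 ],
 "rules": {
  "P": {
   "inputs": [
    "P",
    "Mn"
   ],
   "table": [
    1,
    0,
    2,
    0,
    2,
    1
   ]
  },
  "Mc": "1 if P >= 1 else 0",
  "Mn": "max(Mc, min(P == 0, Dam == 0))",
  "Dam": "0"
 },
 "propensities": {
  "P": {
   "up": 0.9,
   "down": 0.9
  },
  "Mc": {
   "up": 0.9,
   "down": 0.9
  },
  "Mn": {
   "up": 0.9,
   "down": 0.9
  },
  "Dam": {
   "up": 1.0,
   "down": 0.05
  }
 }
}
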