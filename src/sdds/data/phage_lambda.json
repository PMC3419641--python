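{
 "name": "phage_lambda",
 "description": "Four-gene lysis/lysogeny switch. CI rises when CRO is absent or CII is present, else falls; CRO rises toward full expression unless CI is fully expressed, with autorepression at its top level; CII needs N and low CI/CRO; N needs low CI/CRO.",
 "init": "0000",
 "variables": [
  {
   "name": "CI",
   "levels": 3
  },
  {
   "name": "CRO",
   "levels": 4
  },
  {
   "name": "CII",
   "levels": 2
  },
  {
   "name": "N",
   "levels": 2
  }
 ],
 "rules": {
  "CI": {
   "inputs": [
    "CI",
    "CRO",
    "CII"
   ],
   "table": [
    1,
    1,
    0,
    1,
    0,
    1,
    0,
    1,
    2,
    2,
    0,
    2,
    0,
    2,
    0,
    2,
    2,
    2,
    1,
    2,
    1,
    2,
    1,
    2
   ]
  },
  "CRO": {
   "inputs": [
    "CI",
    "CRO"
   ],
   "table": [
    1,
    2,
    3,
    2,
    1,
    2,
    3,
    2,
    0,
    0,
    1,
    2
   ]
  },
  "CII": "min(N, CI < 2, CRO < 2)",
  "N": "min(CI < 2, CRO < 2)"
 },
 "propensities": {
  "CI": {
   "up": 0.8,
   "down": 0.2
  },
  "CRO": {
   "up": 0.2,
   "down": 0.8
  },
  "CII": {
   "up": 0.9,
   "down": 0.9
  },
  "N": {
   "up": 0.9,
   "down": 0.9
  }
 }
}
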