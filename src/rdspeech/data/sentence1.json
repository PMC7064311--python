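{
 "duration": 1.64,
 "frame_rate": 146.0,
 "events": [
  {
   "label": "d",
   "delta": [
    -1.0,
    1.0,
    1.0
   ],
   "mu": 1.1,
   "tp": 0.14,
   "tw": 0.1,
   "th": 0.0,
   "consonant": true
  },
  {
   "label": "ao",
   "delta": [
    1.0,
    -1.0,
    0.0
   ],
   "mu": 0.5,
   "tp": 0.34,
   "tw": 0.21,
   "th": 0.0,
   "consonant": false
  },
  {
   "label": "g",
   "delta": [
    -1.0,
    1.0,
    -1.0
   ],
   "mu": 1.0,
   "tp": 0.55,
   "tw": 0.14,
   "th": 0.03,
   "consonant": true
  },
  {
   "label": "eh",
   "delta": [
    -1.0,
    1.0,
    1.0
   ],
   "mu": 0.5,
   "tp": 0.79,
   "tw": 0.21,
   "th": 0.0,
   "consonant": false
  },
  {
   "label": "ih",
   "delta": [
    -1.0,
    1.0,
    1.0
   ],
   "mu": 0.6,
   "tp": 0.86,
   "tw": 0.21,
   "th": 0.0,
   "consonant": false
  },
  {
   "label": "t",
   "delta": [
    -1.0,
    1.0,
    1.0
   ],
   "mu": 1.0,
   "tp": 0.92,
   "tw": 0.1,
   "th": 0.0,
   "consonant": true
  },
  {
   "label": "b",
   "delta": [
    -1.0,
    -1.0,
    -1.0
   ],
   "mu": 1.0,
   "tp": 1.13,
   "tw": 0.07,
   "th": 0.03,
   "consonant": true
  },
  {
   "label": "ah",
   "delta": [
    1.0,
    -1.0,
    0.0
   ],
   "mu": 0.5,
   "tp": 1.27,
   "tw": 0.24,
   "th": 0.0,
   "consonant": false
  },
  {
   "label": "g",
   "delta": [
    -1.0,
    1.0,
    -1.0
   ],
   "mu": 1.0,
   "tp": 1.47,
   "tw": 0.14,
   "th": 0.01,
   "consonant": true
  }
 ],
 "f0": [
  [
   0.0,
   104.0
  ],
  [
   0.55,
   126.0
  ],
  [
   1.05,
   116.0
  ],
  [
   1.64,
   92.0
  ]
 ],
 "abduction": [
  [
   0.85,
   1.01
  ]
 ]
}
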