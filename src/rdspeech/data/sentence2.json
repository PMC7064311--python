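{
 "duration": 1.64,
 "frame_rate": 146.0,
 "events": [
  {
   "label": "f",
   "delta": [
    -1.0,
    -1.0,
    0.0
   ],
   "mu": 0.98,
   "tp": 0.1,
   "tw": 0.1,
   "th": 0.03,
   "consonant": true
  },
  {
   "label": "r",
   "delta": [
    -0.3,
    0.0,
    -1.0
   ],
   "mu": 0.8,
   "tp": 0.21,
   "tw": 0.1,
   "th": 0.03,
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
   "tw": 0.17,
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
   "tp": 0.58,
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
   "label": "f",
   "delta": [
    -1.0,
    -1.0,
    0.0
   ],
   "mu": 0.98,
   "tp": 1.13,
   "tw": 0.1,
   "th": 0.03,
   "consonant": true
  },
  {
   "label": "l",
   "delta": [
    -0.3,
    0.0,
    1.0
   ],
   "mu": 0.9,
   "tp": 1.23,
   "tw": 0.1,
   "th": 0.0,
   "consonant": true
  },
  {
   "label": "aa",
   "delta": [
    1.0,
    0.0,
    0.0
   ],
   "mu": 0.5,
   "tp": 1.37,
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
   "tp": 1.47,
   "tw": 0.21,
   "th": 0.0,
   "consonant": false
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
   0.02,
   0.18
  ],
  [
   0.85,
   1.01
  ],
  [
   1.05,
   1.21
  ]
 ]
}
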