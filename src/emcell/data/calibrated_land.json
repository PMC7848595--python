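{
 "torord": {
  "params": {
   "n_tm": 2.0,
   "k_tm": 0.02
  },
  "cost": 0.0,
  "achieved": {
   "amplitude": 23.848271935286334,
   "tp": 170.0,
   "rt50": 114.01503607228187,
   "rt95": 265.9078013059486
  },
  "targets": {
   "amplitude": [
    10.1,
    25.6
   ],
   "tp": [
    137.0,
    179.0
   ],
   "rt50": [
    101.0,
    133.0
   ],
   "rt95": [
    248.0,
    539.0
   ]
  },
  "n_evaluations": 29,
  "provenance": "scripts/calibrate.py (bounded Nelder-Mead on coupled 1 Hz twitch biomarkers)"
 },
 "ord": {
  "params": {
   "n_tm": 2.5,
   "k_tm": 0.02
  },
  "cost": 0.0,
  "achieved": {
   "amplitude": 18.3842245369099,
   "tp": 175.5,
   "rt50": 125.86891218789145,
   "rt95": 290.1127486863412
  },
  "targets": {
   "amplitude": [
    10.1,
    25.6
   ],
   "tp": [
    137.0,
    179.0
   ],
   "rt50": [
    101.0,
    133.0
   ],
   "rt95": [
    248.0,
    539.0
   ]
  },
  "n_evaluations": 29,
  "provenance": "scripts/calibrate.py (bounded Nelder-Mead on coupled 1 Hz twitch biomarkers)"
 }
}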