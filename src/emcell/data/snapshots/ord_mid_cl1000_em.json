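{
 "state_version": 1,
 "meta": {
  "variant": "ord",
  "celltype": "mid",
  "cl": 1000.0,
  "coupled": true,
  "converged": true,
  "pre_pacing_beats": 600,
  "criterion": "relative spread of APD90/CaT peak/Ta peak < 5e-4 over 10 beats",
  "mech_params": {
   "n_tm": 2.5,
   "k_tm": 0.02
  }
 },
 "state": [
  -87.61684380204174,
  9.155716304666885,
  9.15584119146375,
  142.66707642886118,
  142.66703599639382,
  8.975222704065086e-05,
  8.684748364292163e-05,
  2.1020614974445126,
  2.052036111495612,
  0.007634039710153841,
  0.6846083693078634,
  0.6846078984297901,
  0.6846003789199142,
  0.4393720966912534,
  0.6845896286984412,
  0.00020254627574834832,
  0.48474565369290246,
  0.24968152241837513,
  0.0010274174948294984,
  0.9995231546141105,
  0.5564442239728332,
  0.0005235037106009345,
  0.9995231549244062,
  0.6041010257867163,
  2.563840596104928e-09,
  0.9999999898747247,
  0.8753641406290158,
  0.9999999898747279,
  0.9996064666261752,
  0.9999533017236447,
  0.9999999898745362,
  0.9999999898745511,
  0.0029909913439464266,
  8.727191621360177e-06,
  0.4853433441269197,
  0.3280245886160018,
  0.00020128280560552863,
  0.9968590664549658,
  1.8086616626142395e-06,
  2.260491889117977e-06,
  0.02530926376205314,
  0.000145391362282576,
  0.00021159130026456133,
  0.01227690322956495,
  0.9994314566088437,
  0.0,
  0.0
 ]
}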