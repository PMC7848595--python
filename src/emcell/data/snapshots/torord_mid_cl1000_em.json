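{
 "state_version": 1,
 "meta": {
  "variant": "torord",
  "celltype": "mid",
  "cl": 1000.0,
  "coupled": true,
  "converged": true,
  "pre_pacing_beats": 450,
  "criterion": "relative spread of APD90/CaT peak/Ta peak < 5e-4 over 10 beats",
  "mech_params": {
   "n_tm": 2.0,
   "k_tm": 0.02
  }
 },
 "state": [
  -88.96035266032098,
  14.565050217757914,
  14.56548880664118,
  141.64608415208363,
  141.64602524270367,
  7.219185356535185e-05,
  5.9216077071981335e-05,
  1.6999830258044515,
  1.7033110802514302,
  0.0007723426803359273,
  0.8324710223824348,
  0.6770736345609095,
  0.832498840341723,
  0.8321161432839022,
  0.0001569280967887322,
  0.527246401296179,
  0.2790887984768372,
  0.0009384552819795921,
  0.9996230993389404,
  0.5612110767254959,
  0.00047815359140003126,
  0.9996230964602488,
  0.6200656441706678,
  3e-323,
  0.9999999929611934,
  0.9203829579705777,
  0.9999999929611746,
  0.9997628167164448,
  0.9999730302801025,
  0.9999999929620955,
  0.9999999929620489,
  0.0003417546762137451,
  0.0007358905136404119,
  0.2676193086826431,
  0.0001731537980347772,
  0.9978224269606515,
  0.0008391224088192533,
  0.0007094107854464635,
  0.0006077354268289729,
  2.130441825377211e-05,
  4.620135222751001e-71,
  1.130993905270868e-57,
  0.01697744943037619,
  0.00016238667737639373,
  0.0002436513003877948,
  0.007970766224908327,
  0.9993501876043566,
  0.0,
  0.0
 ]
}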