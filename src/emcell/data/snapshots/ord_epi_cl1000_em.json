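{
 "state_version": 1,
 "meta": {
  "variant": "ord",
  "celltype": "epi",
  "cl": 1000.0,
  "coupled": true,
  "converged": true,
  "pre_pacing_beats": 450,
  "criterion": "relative spread of APD90/CaT peak/Ta peak < 5e-4 over 10 beats",
  "mech_params": {
   "n_tm": 2.5,
   "k_tm": 0.02
  }
 },
 "state": [
  -87.8791037817852,
  7.960266995008349,
  7.9603430487932405,
  144.07624441886992,
  144.07621014273724,
  7.113387140242287e-05,
  6.962669484825753e-05,
  1.9721671398006064,
  1.9282472932491925,
  0.007435371767965659,
  0.6938380151855207,
  0.6938381785845591,
  0.6938378434555178,
  0.45001601965436283,
  0.6938363177790816,
  0.00019270427710815145,
  0.501200684161326,
  0.27672792181752637,
  0.0010094139097141066,
  0.9995445491472388,
  0.9995384427658397,
  0.0005143257332426624,
  0.9995445491411741,
  0.9995434930368577,
  2.4097087979278166e-09,
  0.9999999905683602,
  0.920832130013528,
  0.99999999056836,
  0.9998826122416749,
  0.9999844021612404,
  0.9999999905683694,
  0.9999999905683696,
  0.0012791951082704509,
  8.180693091008236e-06,
  0.42543007265282035,
  0.24447527175040143,
  0.0001954558902050863,
  0.9967914941570627,
  4.6548808659008557e-07,
  5.817639768371875e-07,
  0.015840571804942933,
  7.943774527382556e-05,
  0.00011870061408964518,
  0.0077419869492839355,
  0.9996831071243808,
  0.0,
  0.0
 ]
}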