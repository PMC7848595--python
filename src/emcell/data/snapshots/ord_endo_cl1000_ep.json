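{
 "state_version": 1,
 "meta": {
  "variant": "ord",
  "celltype": "endo",
  "cl": 1000.0,
  "coupled": false,
  "converged": true,
  "pre_pacing_beats": 400,
  "criterion": "relative spread of APD90/CaT peak/Ta peak < 5e-4 over 10 beats",
  "mech_params": {
   "n_tm": 2.5,
   "k_tm": 0.02
  }
 },
 "state": [
  -87.95759155877941,
  7.504166462054895,
  7.504256192546441,
  144.6305350241296,
  144.6305048472706,
  8.67636629444911e-05,
  8.56240550945949e-05,
  1.6459101480429212,
  1.598630220800938,
  0.007376921740609175,
  0.6965704950588386,
  0.6965601519985359,
  0.6965021930083732,
  0.45317088122262406,
  0.6964632874656401,
  0.000189852972254023,
  0.5000538777959822,
  0.26865272259349077,
  0.0010040905551803312,
  0.9995507279134072,
  0.5847650214510961,
  0.0005116119922007912,
  0.9995507324666832,
  0.6366528927322264,
  2.365430194047074e-09,
  0.9999999907654342,
  0.9022485989291541,
  0.999999990765473,
  0.9997778825033495,
  0.9999727179834529,
  0.9999999907636595,
  0.9999999907637659,
  0.0028364412709238665,
  8.13289839087961e-06,
  0.4556603967449801,
  0.2857366007277864,
  0.0001937832540975283,
  0.9967712270947253,
  2.672821525622183e-07,
  3.33939574680501e-07,
  0.013070131964634604,
  0.0001399300686721696,
  0.00019788893136948212,
  0.011551814118128103,
  0.9994651513719028,
  0.0,
  0.0
 ]
}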