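{
 "state_version": 1,
 "meta": {
  "variant": "torord",
  "celltype": "endo",
  "cl": 1000.0,
  "coupled": false,
  "converged": true,
  "pre_pacing_beats": 200,
  "criterion": "relative spread of APD90/CaT peak/Ta peak < 5e-4 over 10 beats",
  "mech_params": {
   "n_tm": 2.0,
   "k_tm": 0.02
  }
 },
 "state": [
  -88.8980376171289,
  12.071055874319269,
  12.071383450288044,
  142.53050538816228,
  142.53046243583842,
  7.301873775169442e-05,
  6.3877261474501e-05,
  1.4884011046516659,
  1.4854226985861265,
  0.0007827762647742604,
  0.8312294324219266,
  0.6750338200832325,
  0.8310395020991242,
  0.8306745625612761,
  0.00015879677968503868,
  0.52930160197345,
  0.28978310087847137,
  0.0009424132338166104,
  0.9996188878385242,
  0.5943856193164168,
  0.00048017114571964343,
  0.9996188956451149,
  0.6550525877291254,
  3e-323,
  0.9999999928392868,
  0.9398098354377099,
  0.9999999928393395,
  0.9999017109491274,
  0.9999843628081521,
  0.9999999928365624,
  0.9999999928367154,
  0.000458820521468023,
  0.0007694299612016788,
  0.24574662767696093,
  0.0001744514758636144,
  0.998079100646217,
  0.000843013500335829,
  0.0006966909462651978,
  0.00036826378227603537,
  1.2931124905990853e-05,
  9.732373057740406e-77,
  3.906894654822657e-62,
  0.010791865465157294,
  0.0001713186361050345,
  0.0002509341324447266,
  0.008180614747257776,
  0.9993271780861567,
  0.0,
  0.0
 ]
}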