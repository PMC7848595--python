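{
 "state_version": 1,
 "meta": {
  "variant": "torord",
  "celltype": "endo",
  "cl": 4000.0,
  "coupled": false,
  "converged": false,
  "pre_pacing_beats": 1500,
  "criterion": "relative spread of APD90/CaT peak/Ta peak < 5e-4 over 10 beats",
  "mech_params": {
   "n_tm": 2.0,
   "k_tm": 0.02
  }
 },
 "state": [
  -85.04082598671857,
  8.840425832494116,
  8.840645959484377,
  125.45553616630086,
  125.45552885013767,
  6.542386792359928e-05,
  5.851775929088379e-05,
  1.187933032508681,
  1.1896142748574687,
  0.0017856856521993125,
  0.7396895617705433,
  0.5367978508496074,
  0.7396879843404407,
  0.7396873751101396,
  0.00033036747765424735,
  0.4150515331574104,
  0.23640758482502158,
  0.0012222258394488912,
  0.9992515679664395,
  0.9839560917913232,
  0.0006228246733509591,
  0.999251568063983,
  0.990009455551197,
  3e-323,
  0.9999999796718754,
  0.9970102189905734,
  0.9999999796718771,
  0.9999999796715416,
  0.999999999961675,
  0.9999999796718143,
  0.9999999796718189,
  0.00032641041947363396,
  0.0005031108271117129,
  0.04310405997910314,
  0.00026854801689039313,
  0.9977555937663237,
  0.0011091820849767316,
  0.0008960234072442928,
  0.00022939272193788038,
  9.808019517542267e-06,
  6.67e-322,
  9.287785201403529e-279,
  0.0008329680279181818,
  0.0001338869619308675,
  0.000200781468305667,
  0.0065620842883369265,
  0.9994645552326978,
  0.0,
  0.0
 ]
}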