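{
 "state_version": 1,
 "meta": {
  "variant": "torord",
  "celltype": "endo",
  "cl": 1000.0,
  "coupled": true,
  "converged": true,
  "pre_pacing_beats": 300,
  "criterion": "relative spread of APD90/CaT peak/Ta peak < 5e-4 over 10 beats",
  "mech_params": {
   "n_tm": 2.0,
   "k_tm": 0.02
  }
 },
 "state": [
  -88.92867152609143,
  11.96444402159195,
  11.964754109753706,
  142.7686523095801,
  142.76861128310645,
  7.113895736928782e-05,
  6.218433956925035e-05,
  1.4920617499112434,
  1.4929122197267362,
  0.0007776292894550953,
  0.8318476702642446,
  0.6760489429825658,
  0.8318808815787919,
  0.8317112995771239,
  0.0001578752673438584,
  0.5324276899063995,
  0.2937823656756057,
  0.0009404619545318069,
  0.9996210009289319,
  0.5959649704727187,
  0.00047917648585757346,
  0.9996209983797099,
  0.6584663635288184,
  3e-323,
  0.9999999929005228,
  0.9406513236011637,
  0.999999992900506,
  0.9999009951984078,
  0.9999852552680684,
  0.999999992901329,
  0.999999992901287,
  0.00041318684109728493,
  0.0006953346284760205,
  0.2394791740787476,
  0.00017377140194163452,
  0.9981016706796327,
  0.0008411900624902236,
  0.0006940883788665008,
  0.00035075682011107104,
  1.229405889945804e-05,
  6.923652797476888e-77,
  2.8708850259617765e-62,
  0.010903118714501022,
  0.00015724953382728653,
  0.00023668038621816798,
  0.007742478417222041,
  0.9993692806036332,
  0.0,
  0.0
 ]
}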