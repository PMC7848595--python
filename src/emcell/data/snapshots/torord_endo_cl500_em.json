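{
 "state_version": 1,
 "meta": {
  "variant": "torord",
  "celltype": "endo",
  "cl": 500.0,
  "coupled": true,
  "converged": true,
  "pre_pacing_beats": 550,
  "criterion": "relative spread of APD90/CaT peak/Ta peak < 5e-4 over 10 beats",
  "mech_params": {
   "n_tm": 2.0,
   "k_tm": 0.02
  }
 },
 "state": [
  -89.46733648968367,
  13.39036863702381,
  13.390705300928659,
  142.87926096281598,
  142.87918779252138,
  6.631590251570798e-05,
  5.922069777207165e-05,
  1.7026707854020982,
  1.5907377077247935,
  0.0006924123687384565,
  0.8421329275326105,
  0.6931076558104108,
  0.8327879321149829,
  0.8054391004180879,
  0.0001425218292112473,
  0.44704152860140645,
  0.2227032615081088,
  0.000906944995218933,
  0.9996548609792538,
  0.30564654535795444,
  0.00046209159499774484,
  0.9996548956988974,
  0.36459489363795194,
  2.343808597172561e-227,
  0.9999999938568332,
  0.8750589973676989,
  0.9999999938570386,
  0.9922154342568092,
  0.9928869018637452,
  0.9999999283236507,
  0.9999999903471758,
  0.00034541923614667835,
  0.0005350181685067734,
  0.3697288955133445,
  0.0001671123329965243,
  0.9600692933878414,
  0.000787138408179857,
  0.002982423221702629,
  0.034964930506396645,
  0.0011962144758794358,
  7.642561388250121e-36,
  1.4508216485731415e-29,
  0.04052556205837495,
  0.0007331192763671698,
  0.00022934579232261303,
  0.0068150434900707295,
  0.9988114477369159,
  0.0,
  0.0
 ]
}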