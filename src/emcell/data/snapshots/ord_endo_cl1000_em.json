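{
 "state_version": 1,
 "meta": {
  "variant": "ord",
  "celltype": "endo",
  "cl": 1000.0,
  "coupled": true,
  "converged": true,
  "pre_pacing_beats": 350,
  "criterion": "relative spread of APD90/CaT peak/Ta peak < 5e-4 over 10 beats",
  "mech_params": {
   "n_tm": 2.5,
   "k_tm": 0.02
  }
 },
 "state": [
  -87.97805676557464,
  7.440832538124419,
  7.440910038083634,
  144.7026076277517,
  144.70257784312767,
  7.895249824467886e-05,
  7.729061368674774e-05,
  1.636853087135407,
  1.603132191736168,
  0.007361753441260461,
  0.6972809538177107,
  0.6972807317094434,
  0.6972776491013676,
  0.45404179774799475,
  0.6972736013326601,
  0.00018911632874885818,
  0.5012332547102025,
  0.2697730976283638,
  0.001002703359107005,
  0.9995523682741334,
  0.5855645908439095,
  0.0005109048293599967,
  0.9995523684092928,
  0.6377017031024832,
  2.353993123002169e-09,
  0.9999999908174866,
  0.9029188043328212,
  0.9999999908174879,
  0.999781108809355,
  0.9999737284072574,
  0.9999999908174135,
  0.9999999908174183,
  0.0019129401200891534,
  8.102342242299035e-06,
  0.4548840470275808,
  0.28262557307947667,
  0.00019330453829325683,
  0.9967656394491463,
  2.684510326736826e-07,
  3.3543974799472984e-07,
  0.013107204197818245,
  0.00010336002348292893,
  0.00015393784945525986,
  0.009525662259972426,
  0.9995887558562314,
  0.0,
  0.0
 ]
}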