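{
 "state_version": 1,
 "meta": {
  "variant": "torord",
  "celltype": "epi",
  "cl": 1000.0,
  "coupled": true,
  "converged": true,
  "pre_pacing_beats": 400,
  "criterion": "relative spread of APD90/CaT peak/Ta peak < 5e-4 over 10 beats",
  "mech_params": {
   "n_tm": 2.0,
   "k_tm": 0.02
  }
 },
 "state": [
  -89.10118744057327,
  12.67279646964955,
  12.673087723279783,
  142.5283573016312,
  142.52830956743875,
  6.331919386755911e-05,
  5.525348862060549e-05,
  1.738085578541717,
  1.738029574178598,
  0.0007492675254389072,
  0.8352157482419551,
  0.6815995490583205,
  0.8352509537500914,
  0.8351498697547326,
  0.00015278589930119792,
  0.5402173095843845,
  0.30468043819462076,
  0.0009295878999147575,
  0.9996322570030668,
  0.9996298509432503,
  0.00047363349790798735,
  0.9996322568297907,
  0.9996320463370978,
  3e-323,
  0.999999993224278,
  0.9490827547348599,
  0.9999999932242625,
  0.9999343108651965,
  0.9999883579301526,
  0.9999999932250356,
  0.9999999932249969,
  0.0002610653016506784,
  0.0004431566868197812,
  0.2263314911475664,
  0.0001704481589149739,
  0.9982056221799984,
  0.0008309837117587526,
  0.0006810066205413913,
  0.00027291893441776395,
  9.468553283738803e-06,
  8.635408320008608e-80,
  8.59314436424817e-65,
  0.012521045644578992,
  0.00012454356759085308,
  0.00018771866686168327,
  0.006141831074920932,
  0.9994998997113075,
  0.0,
  0.0
 ]
}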