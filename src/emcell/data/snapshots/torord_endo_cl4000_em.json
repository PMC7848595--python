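{
 "state_version": 1,
 "meta": {
  "variant": "torord",
  "celltype": "endo",
  "cl": 4000.0,
  "coupled": true,
  "converged": false,
  "pre_pacing_beats": 1500,
  "criterion": "relative spread of APD90/CaT peak/Ta peak < 5e-4 over 10 beats",
  "mech_params": {
   "n_tm": 2.0,
   "k_tm": 0.02
  }
 },
 "state": [
  -85.03964328419592,
  8.77147481181265,
  8.771692745051158,
  125.52408612923506,
  125.5240798167768,
  6.529227692422499e-05,
  5.8429204407788926e-05,
  1.1855526058309744,
  1.1872185202559367,
  0.001786133705241865,
  0.7396565476723563,
  0.5367520854782112,
  0.7396544722438135,
  0.7396535956869541,
  0.0003304416883913915,
  0.4150114425468061,
  0.23640437294811173,
  0.001222323279822095,
  0.9992514128288406,
  0.9841410628380313,
  0.0006228743570433597,
  0.999251412952191,
  0.9901706095143448,
  3e-323,
  0.9999999796653692,
  0.9971624684116277,
  0.999999979665371,
  0.9999999796648548,
  0.9999999999616526,
  0.9999999796653082,
  0.9999999796653127,
  0.0003244958722234016,
  0.0004992050155048872,
  0.04144777990758844,
  0.00026858378425441925,
  0.9977553818653723,
  0.0011092753106663712,
  0.0008960988490772632,
  0.00022943359220082166,
  9.810382683351038e-06,
  6.6e-322,
  2.7413379259309393e-279,
  0.0008406594573642586,
  0.00013335872298189398,
  0.00019998259016056465,
  0.006535923891386381,
  0.9994666818552166,
  0.0,
  0.0
 ]
}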