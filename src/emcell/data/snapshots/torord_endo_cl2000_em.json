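{
 "state_version": 1,
 "meta": {
  "variant": "torord",
  "celltype": "endo",
  "cl": 2000.0,
  "coupled": true,
  "converged": true,
  "pre_pacing_beats": 350,
  "criterion": "relative spread of APD90/CaT peak/Ta peak < 5e-4 over 10 beats",
  "mech_params": {
   "n_tm": 2.0,
   "k_tm": 0.02
  }
 },
 "state": [
  -88.49825035696958,
  10.661857663640863,
  10.662130359506408,
  142.3253610579546,
  142.32534237344743,
  7.045640297468543e-05,
  6.210111193794088e-05,
  1.3401518540619723,
  1.3428322711737375,
  0.0008530862777458238,
  0.8231868572082951,
  0.6619330112654531,
  0.8231974148122085,
  0.8232031639604862,
  0.0001713244371172066,
  0.5296026176371386,
  0.3215703340196749,
  0.0009681512159252617,
  0.9995913290747982,
  0.872999779809096,
  0.0004932911977556781,
  0.999591328459076,
  0.9089089114095243,
  3e-323,
  0.9999999920232115,
  0.981060458996437,
  0.9999999920232071,
  0.9999999852230869,
  0.999999999964936,
  0.9999999920234347,
  0.9999999920234223,
  0.00041108835726752914,
  0.0006700101162504655,
  0.11842781579946028,
  0.00018236390949640446,
  0.9982889421139997,
  0.0008674899441871312,
  0.0007007753408984625,
  0.00013788454163568775,
  4.908059279257252e-06,
  3.165808795697774e-166,
  1.0485690076062025e-133,
  0.0032225492071712553,
  0.00015483190789544998,
  0.00023249343753940028,
  0.0076007984483155286,
  0.9993801584995315,
  0.0,
  0.0
 ]
}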