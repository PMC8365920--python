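{
 "schema": "planargait-reflex-v1",
 "params": {
  "contact_thresh": 0.1922306930989006,
  "pitch_setpoint": -0.01895294689374572,
  "sol_offset": 0.0034476293163741597,
  "sol_gain": 0.06140314197978576,
  "gas_offset": 0.021200690750531652,
  "gas_gain": 0.42588476312689916,
  "vas_offset": 0.3081075274536142,
  "vas_gain": 0.33900687239406657,
  "glu_offset": 0.14693657268393076,
  "glu_pitch_gain": 0.9268323765322658,
  "glu_dpitch_gain": 0.423130870225293,
  "ham_pitch_gain": 1.6437463977150784,
  "hfl_pitch_gain": 0.5524341916637658,
  "ta_offset": 0.08824923386992801,
  "ta_sol_gain": 0.5957136813452028,
  "hfl_offset_sw": 0.91801317267922,
  "hfl_length_gain": 0.9478091863569122,
  "ham_sw_gain": 1.1657685326106906,
  "glu_offset_sw": 0.31221049270584467,
  "bfsh_offset_sw": 0.20639925045937713,
  "ta_offset_sw": 0.3545449084542847,
  "swing_time_knee": 0.28489643956151733,
  "init_swing_time": 0.12309160658069793
 }
}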