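# Maximum-a-posteriori division and conversion rates for the SAN model,
# in expected events per cell per day, over the four culture phases.
intervals:
- t_start: 0.0
  t_end: 3.0
  s_ss: 0.0
  s_del: 0.35
  s_a: 0.0
  s_n: 0.15
  a_an: 0.0
  a_n: 0.0
- t_start: 3.0
  t_end: 6.0
  s_ss: 0.6
  s_del: 0.0
  s_a: 0.0
  s_n: 0.15
  a_an: 0.0
  a_n: 0.0
- t_start: 6.0
  t_end: 11.0
  s_ss: 0.94
  s_del: 0.0
  s_a: 0.0
  s_n: 1.14
  a_an: 0.0
  a_n: 0.0
- t_start: 11.0
  t_end: 40.0
  s_ss: 1.68
  s_del: 0.0
  s_a: 1.69
  s_n: 0.0
  a_an: 0.71
  a_n: 0.07
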