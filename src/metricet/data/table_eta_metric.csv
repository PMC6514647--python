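doy,location,eta_mm_day
178,S-E,7.98
178,S,8.06
178,N,7.68
178,E,8.45
178,E-E,8.22
194,S-E,9.40
194,S,9.41
194,N,8.87
194,E,9.72
194,E-E,9.45
202,S-E,7.16
202,S,7.08
202,N,7.10
202,E,7.14
202,E-E,7.26
218,S-E,4.63
218,S,4.63
218,N,4.56
218,E,4.82
218,E-E,4.92
234,S-E,3.91
234,S,3.96
234,N,3.93
234,E,4.23
234,E-E,4.23
258,S-E,2.69
258,S,2.87
258,N,2.75
258,E,2.60
258,E-E,2.67
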