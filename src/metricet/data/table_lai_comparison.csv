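doy,location,estimated,measured
178,S-E,3.6,4.5
178,S,4.0,4.8
178,N,3.8,4.7
178,E,4.1,5.0
178,E-E,3.8,4.9
194,S-E,4.6,5.9
194,S,6.0,7.0
194,N,4.7,6.6
194,E,5.5,6.8
194,E-E,5.3,6.4
202,S-E,6.0,5.8
202,S,6.0,6.7
202,N,6.0,6.4
202,E,6.0,6.8
202,E-E,6.0,6.1
218,S-E,6.0,5.9
218,S,6.0,7.0
218,N,6.0,5.9
218,E,6.0,6.7
218,E-E,6.0,6.3
234,S-E,6.0,4.7
234,S,6.0,6.2
234,N,6.0,5.7
234,E,6.0,5.2
234,E-E,6.0,5.7
258,S-E,1.3,3.0
258,S,2.6,3.7
258,N,2.4,3.4
258,E,2.3,3.3
258,E-E,2.5,3.8
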