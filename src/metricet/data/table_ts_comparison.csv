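doy,location,estimated,measured
194,S-E,26.4,25.6
194,S,26.4,24.5
194,N,25.9,24.7
194,E,25.9,23.9
194,E-E,25.9,24.0
202,S-E,29.5,31.0
202,S,28.2,30.1
202,N,27.7,29.7
202,E,26.9,28.9
202,E-E,28.3,30.2
218,S-E,26.7,25.3
218,S,26.6,24.6
218,N,26.9,25.1
218,E,26.2,24.5
218,E-E,26.1,24.4
234,S-E,24.8,23.8
234,S,24.6,22.8
234,N,24.7,23.5
234,E,24.2,23.5
234,E-E,24.2,22.8
258,S-E,20.9,19.7
258,S,21.2,19.2
258,N,20.9,19.4
258,E,20.9,20.4
258,E-E,20.8,19.7
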