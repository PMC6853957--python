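method,peak_id
gca,P1
gca,P2
gca,P3
gca,P4
gca,P5
gca,P8
gca,P10
gca,P11
gca,N1
gca,N3
gca,N4
gca,N6
gca,N8
gca,N9
gca,N10
gca,N11
gca,N12
bca,P10
bca,P12
bca,N6
bca,N8
bca,N9
bca,N11
bca,N14
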