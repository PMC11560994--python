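environment,mean,ipca1,ipca2
Kobierzyce,13.66,-1.197,1.110
Mikulice,12.95,-0.555,0.878
Płaczkowo,14.01,0.897,0.655
Radzików,13.49,-1.101,-2.092
Smolice,11.81,1.957,-0.550
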