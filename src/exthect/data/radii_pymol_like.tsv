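element	radius
C	1.90
N	1.65
O	1.50
S	1.85
P	1.90
H	1.20
SE	1.95
default	1.90
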