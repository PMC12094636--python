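item,factor
P1,positive
P3,positive
P5,positive
G9,positive
N1,negative
N2,negative
N3,negative
N4,negative
N6,negative
G7,negative
P2,disorganized
N5,disorganized
G11,disorganized
P4,excited
P7,excited
G8,excited
G14,excited
G2,depressed
G3,depressed
G6,depressed
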