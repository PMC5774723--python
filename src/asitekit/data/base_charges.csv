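restype,atom,charge,epsilon,rmin_half
A,N9,-0.0251,0.1700,1.8240
A,C8,0.2006,0.0860,1.9080
A,N7,-0.6073,0.1700,1.8240
A,C5,0.0515,0.0860,1.9080
A,C6,0.7009,0.0860,1.9080
A,N6,-0.9019,0.1700,1.8240
A,N1,-0.7615,0.1700,1.8240
A,C2,0.5875,0.0860,1.9080
A,N3,-0.6997,0.1700,1.8240
A,C4,0.3053,0.0860,1.9080
G,N9,0.0492,0.1700,1.8240
G,C8,0.1374,0.0860,1.9080
G,N7,-0.5709,0.1700,1.8240
G,C5,0.1744,0.0860,1.9080
G,C6,0.4770,0.0860,1.9080
G,O6,-0.5597,0.2100,1.6612
G,N1,-0.4787,0.1700,1.8240
G,C2,0.7657,0.0860,1.9080
G,N2,-0.9672,0.1700,1.8240
G,N3,-0.6323,0.1700,1.8240
G,C4,0.1222,0.0860,1.9080
C,N1,-0.0484,0.1700,1.8240
C,C2,0.7538,0.0860,1.9080
C,O2,-0.6252,0.2100,1.6612
C,N3,-0.7584,0.1700,1.8240
C,C4,0.8185,0.0860,1.9080
C,N4,-0.9530,0.1700,1.8240
C,C5,-0.5215,0.0860,1.9080
C,C6,0.0053,0.0860,1.9080
U,N1,0.0418,0.1700,1.8240
U,C2,0.4687,0.0860,1.9080
U,O2,-0.5477,0.2100,1.6612
U,N3,-0.3549,0.1700,1.8240
U,C4,0.5952,0.0860,1.9080
U,O4,-0.5761,0.2100,1.6612
U,C5,-0.3635,0.0860,1.9080
U,C6,-0.1126,0.0860,1.9080
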