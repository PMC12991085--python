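offset,HCN1,HCN2,HCN3,HCN4
0,I502,I571,V455,I622
1,I503,I572,V456,I623
5,A507,T576,S460,T627
6,V508,I577,V461,I628
8,K510,K579,R463,K630
17,V519,V588,L472,V639
18,A520,V589,L473,V640
19,G521,S590,S474,S641
21,I523,L592,L476,L643
22,T524,T593,A477,T644
23,K525,K594,R478,K645
24,S526,G595,G479,G646
25,S527,N596,A480,N647
26,K528,K597,R481,K648
27,E529,E598,D482,E649
28,M530,M599,T483,T650
29,K531,K600,R484,K651
31,T533,S602,T486,A653
37,G539,G608,G492,G659
38,E540,E609,E493,E660
40,C542,C611,C495,C662
44,K546,R615,R499,R666
47,R549,R618,R502,R669
48,T550,T619,T503,T670
86,I588,I657,M541,L708
88,R590,R659,R543,R710
90,D592,D661,L545,D712
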