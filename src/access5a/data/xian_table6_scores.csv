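node_id,score
A,3.1544
A1,3.1542
A11,3.1442
A12,3.1651
A2,3.0816
A21,2.9790
A22,3.2372
A3,3.2135
A31,3.2071
A32,3.2234
A33,3.2114
B,3.6724
B1,3.8429
B11,3.8815
B12,3.8116
B2,3.5369
B21,3.4767
B22,3.6022
C,3.2668
C1,3.4173
C11,3.6675
C12,3.3744
C13,3.3099
C2,3.2142
C21,3.2303
C22,3.2976
C23,3.1347
C3,3.0791
C31,3.0837
C32,3.0742
C4,3.4582
C41,3.7348
C42,3.2930
D,3.5627
D1,3.5429
D11,3.6536
D12,3.7349
D13,3.2931
D14,3.5650
D2,3.6026
D21,3.5697
D22,3.6511
E,3.3721
E1,3.3868
E11,3.3838
E12,3.3652
E13,3.4115
E2,3.3210
E21,3.3045
E22,3.3257
E23,3.0862
E24,3.4722
E25,3.5255
E3,3.4971
E31,3.5347
E32,3.4535
overall,3.3330
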