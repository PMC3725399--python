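dose_gy,cells_scored,breaks,aberrant_cells,stable_exchanges,unstable_exchanges,total_aberrations
0,500,26,22,2,2,22
0.1,200,24,19,1,1,22
0.25,200,31,24,2,2,27
0.5,200,40,33,3,2,35
1,200,88,48,15,14,57
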