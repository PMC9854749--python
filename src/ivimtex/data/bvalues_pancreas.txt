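# b-value (s/mm^2)   number of signal averages
0 1
25 1
50 1
75 1
100 1
150 1
200 1
500 2
800 3
1000 3
1250 4
1500 4
2000 5
2500 7
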