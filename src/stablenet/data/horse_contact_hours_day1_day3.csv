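horse,1,2,3,4,5,6,7,8,9
1,,,0.05,6.11,0.67,<0.00,0.01,0.89,
2,<0.00,,5.63,0.23,,4.12,<0.00,5.73,
3,<0.00,0.69,,0.17,,6.24,,,
4,0.24,11.89,0.31,,,<0.00,,21.76,
5,2.82,<0.00,<0.00,,,0.23,1.31,,5.44
6,2.18,1.31,0.46,,0.11,,0.15,<0.00,0.02
7,0.23,,,,0.24,15.04,,,13.92
8,0.23,15.75,0.19,15.92,,<0.00,,,
9,0.13,,,0.01,2.30,3.82,15.58,<0.00,
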