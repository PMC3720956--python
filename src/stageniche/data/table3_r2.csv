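dataset,response,ABIOT,BIOT,FULL
1,PA,0.73,0.53,0.76
2,PA,0.62,0.20,0.65
3,PA,0.81,0.61,0.85
4,PA,0.93,0.16,0.94
5,PA,0.67,0.63,0.76
6,PA,0.67,0.28,0.67
7,PA,0.40,0.13,0.40
8,PA,0.34,0.14,0.35
1,AB,0.91,0.73,0.93
2,AB,0.78,0.20,0.79
3,AB,0.91,0.73,0.94
4,AB,0.94,0.03,0.94
5,AB,0.83,0.64,0.87
6,AB,0.81,0.49,0.82
7,AB,0.55,0.12,0.55
8,AB,0.43,0.15,0.43
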