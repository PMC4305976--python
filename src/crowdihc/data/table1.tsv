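image_id	gold_positivity	crowd_positivity
1	65.83	69.62
2	73.43	69.10
3	47.06	41.26
4	18.33	23.14
5	75.00	68.83
6	67.11	61.90
7	7.88	12.63
8	6.78	8.25
9	7.48	10.71
10	8.33	10.05
11	2.78	2.88
12	46.34	42.66
13	57.97	45.23
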