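aa	panel	lo	hi
Gly	a	1.0	1.0
Ala	a	0.30	2.00
Ile	a	0.05	0.30
Val	a	0.05	0.30
Ser	a	0.02	0.15
Glu	a	0.02	0.15
Pro	a	0.02	0.15
Asp	a	0.02	0.15
Leu	a	0.01	0.05
Phe	a	0.01	0.05
Thr	a	0.01	0.05
Cys	a	0.01	0.05
Met	a	0.01	0.05
Arg	a	0.01	0.05
Lys	a	0.01	0.05
His	a	0.01	0.05
Gly	b	1.0	1.0
Ala	b	0.50	1.50
Ser	b	0.50	1.00
Glu	b	0.50	1.00
Asp	b	0.20	0.80
Val	b	0.10	0.30
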