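aa	classes	noncanonical_sep_route
Ala	II	0
Arg	I	0
Asn	II	0
Asp	II	0
Cys	I	1
Gln	I	0
Glu	I	0
Gly	II	0
His	II	0
Ile	I	0
Leu	I	0
Lys	I,II	0
Met	I	0
Phe	II	0
Pro	II	0
Ser	II	0
Thr	II	0
Trp	I	0
Tyr	I	0
Val	I	0
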