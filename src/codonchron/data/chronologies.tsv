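name	aa	rank
trifonov_consensus	Gly	1
trifonov_consensus	Ala	2
trifonov_consensus	Asp	3
trifonov_consensus	Val	4
trifonov_consensus	Pro	5
trifonov_consensus	Ser	6
trifonov_consensus	Glu	7
trifonov_consensus	Leu	8
trifonov_consensus	Thr	8
trifonov_consensus	Arg	9
trifonov_consensus	Ile	10
trifonov_consensus	Gln	10
trifonov_consensus	Asn	10
trifonov_consensus	His	11
trifonov_consensus	Lys	12
trifonov_consensus	Cys	13
trifonov_consensus	Phe	14
trifonov_consensus	Tyr	15
trifonov_consensus	Met	16
trifonov_consensus	Trp	17
trifonov_n6prime	Ala	1
trifonov_n6prime	Gly	2
trifonov_n6prime	Ser	3
trifonov_n6prime	Pro	4
trifonov_n6prime	Arg	5
trifonov_n6prime	Asp	6
trifonov_n6prime	Thr	7
trifonov_n6prime	Cys	8
trifonov_n6prime	Glu	9
trifonov_n6prime	Val	10
trifonov_n6prime	Trp	10
trifonov_n6prime	His	11
trifonov_n6prime	Leu	12
trifonov_n6prime	Met	13
trifonov_n6prime	Gln	13
trifonov_n6prime	Ile	14
trifonov_n6prime	Asn	15
trifonov_n6prime	Tyr	16
trifonov_n6prime	Phe	17
trifonov_n6prime	Lys	18
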