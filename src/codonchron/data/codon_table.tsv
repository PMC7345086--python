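codon	label
AAA	Lys
AAC	Asn
AAG	Lys
AAU	Asn
ACA	Thr
ACC	Thr
ACG	Thr
ACU	Thr
AGA	Arg
AGC	Ser
AGG	Arg
AGU	Ser
AUA	Ile
AUC	Ile
AUG	Met
AUU	Ile
CAA	Gln
CAC	His
CAG	Gln
CAU	His
CCA	Pro
CCC	Pro
CCG	Pro
CCU	Pro
CGA	Arg
CGC	Arg
CGG	Arg
CGU	Arg
CUA	Leu
CUC	Leu
CUG	Leu
CUU	Leu
GAA	Glu
GAC	Asp
GAG	Glu
GAU	Asp
GCA	Ala
GCC	Ala
GCG	Ala
GCU	Ala
GGA	Gly
GGC	Gly
GGG	Gly
GGU	Gly
GUA	Val
GUC	Val
GUG	Val
GUU	Val
UAA	STOP
UAC	Tyr
UAG	STOP
UAU	Tyr
UCA	Ser
UCC	Ser
UCG	Ser
UCU	Ser
UGA	STOP
UGC	Cys
UGG	Trp
UGU	Cys
UUA	Leu
UUC	Phe
UUG	Leu
UUU	Phe
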