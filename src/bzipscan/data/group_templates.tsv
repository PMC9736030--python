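# bzipscan DNA-binding specificity group templates, v1
# 30-column signature window: cols 1-11 = residues upstream of the invariant
# Asn, col 12 = Asn anchor, cols 13-19 = x7 spacer, col 20 = R/K anchor,
# cols 21-30 = hinge/downstream context. '*' matches anything; (X/Y) matches
# either letter. priority breaks ties among groups with equal fixed-column
# match counts (lower value wins).
group	template	priority	binding_site
D	********LAQN**AA*KSR***KAYVQQ*	1	C-box sequence
B	**********RNRESAQLSR**********	2	G- and C-boxes with equal affinity
H	***********NRVSAQQAR**********	3	G-box-like sequences
A	*********MIK************QAY***	4	ABREs with the core ACGT or others containing GCGT/AAGT
G/M/S	***********N**SA**SR**********	5	G-box and/or G-box-like sequences
C	***********************QAHLEE*	6	Hybrid ACGT elements such as G/C, G/A, and C/G boxes
E	*********A**************QYI(S/A)E*	7	Unknown
I	*******************K**********	8	Sequences other than those containing a palindromic ACGT core, such as CCA/TGG repeats
J	*******************I**********	9	Unknown
F/K	**************A***************	10	C-box elements
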