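# RNA Watson-Crick nearest-neighbor stack free energies, Delta-G at 37 C
# (kcal/mol). Values from the standard published set of Xia et al. (1998),
# Biochemistry 37:14719 (as used in the Turner 2004 rules).
# Each row: the 5'->3' dinucleotide on one strand of a perfect duplex; the
# paired dinucleotide on the opposite strand is its reverse complement, so
# symmetric stacks share one value (e.g. AA/UU and UU/AA are both -0.93).
# Stack-only values; duplex initiation and terminal-AU penalties are not
# included here.
AA	-0.93
UU	-0.93
AU	-1.10
UA	-1.33
CU	-2.08
AG	-2.08
CA	-2.11
UG	-2.11
GU	-2.24
AC	-2.24
GA	-2.35
UC	-2.35
CG	-2.36
GG	-3.26
CC	-3.26
GC	-3.42
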