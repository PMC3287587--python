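# Elastic constants k (eV/nm^2) for the ten unique nearest-neighbour
# dimer steps of duplex DNA.  The remaining six dimers are resolved at
# load time through reverse-complement equivalence (e.g. TpT -> ApA).
# Columns: dimer <TAB> k
AA	2.40
AC	2.56
AG	2.25
AT	1.83
CA	3.44
CC	2.06
CG	2.74
GA	2.80
GC	3.36
TA	2.42
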