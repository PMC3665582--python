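# Generic sidechain torsion parameters: E = k (1 + cos(n*psi + phase)).
# sp3 chis prefer staggered rotamers (minimum at +-60/180 deg); planar
# chis (aromatic rings, amide/carboxylate/guanidinium planes) use a
# two-fold term with its minima at +-90 deg.
# class	k	n	phase
sp3	1.40	3	0
planar	1.25	2	180
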