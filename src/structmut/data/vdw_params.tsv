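# Per-element Lennard-Jones parameters and hard-sphere vdW radii for
# heavy atoms.  Rmin_half and epsilon follow common molecular-mechanics
# magnitudes for united heavy atoms; vdw_radius is the Bondi-style radius
# used by the legacy overlap count.  Values are configurable by passing an
# alternative table path.
# element	rmin_half	epsilon	vdw_radius
C	2.000	0.110	1.70
N	1.850	0.200	1.55
O	1.700	0.120	1.52
S	2.000	0.450	1.80
P	2.150	0.585	1.80
F	1.700	0.100	1.47
CL	1.910	0.300	1.75
BR	1.980	0.320	1.85
I	2.090	0.400	1.98
FE	1.456	0.013	1.45
ZN	1.090	0.250	1.39
MG	1.185	0.015	1.73
CA	1.367	0.120	1.70
*	2.000	0.110	1.70
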