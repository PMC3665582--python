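# Kyte-Doolittle hydropathy index and the three-way polarity class used
# by the core/surface analyses.
# aa	kd	class
A	1.8	phobic
R	-4.5	philic
N	-3.5	philic
D	-3.5	philic
C	2.5	phobic
Q	-3.5	philic
E	-3.5	philic
G	-0.4	neutral
H	-3.2	philic
I	4.5	phobic
L	3.8	phobic
K	-3.9	philic
M	1.9	phobic
F	2.8	phobic
P	-1.6	neutral
S	-0.8	philic
T	-0.7	philic
W	-0.9	phobic
Y	-1.3	neutral
V	4.2	phobic
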