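ligand	score
F-R-AMC	-9.8
Y-R-AMC	-9.7
P-R-AMC	-8.9
H-R-AMC	-8.5
R-R-AMC	-8.4
W-R-AMC	-8.4
V-R-AMC	-8.4
A-R-AMC	-8.3
N-R-AMC	-8.3
I-R-AMC	-8.3
D-R-AMC	-8.2
Q-R-AMC	-8.2
L-R-AMC	-8.1
C-R-AMC	-8.1
E-R-AMC	-8.0
T-R-AMC	-8.0
G-R-AMC	-7.8
K-R-AMC	-7.6
M-R-AMC	-7.6
S-R-AMC	-7.6
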