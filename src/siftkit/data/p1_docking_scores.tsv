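ligand	score
R-AMC	-10.4
F-AMC	-8.3
Y-AMC	-7.9
W-AMC	-7.5
N-AMC	-7.2
P-AMC	-6.9
H-AMC	-6.4
L-AMC	-6.4
V-AMC	-6.4
A-AMC	-6.2
Q-AMC	-6.2
E-AMC	-6.2
G-AMC	-6.2
C-AMC	-6.1
I-AMC	-6.1
K-AMC	-6.1
T-AMC	-6.1
M-AMC	-5.9
S-AMC	-5.9
D-AMC	-5.5
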