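# Amino-acid background frequencies (natural protein composition) used as
# the default background q(b) for log-odds scoring, pseudocount correction
# and Kullback-Leibler logos.
A	0.074
C	0.025
D	0.054
E	0.054
F	0.047
G	0.074
H	0.026
I	0.068
K	0.058
L	0.099
M	0.025
N	0.045
P	0.039
Q	0.034
R	0.052
S	0.057
T	0.051
V	0.073
W	0.013
Y	0.032
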