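# Side-chain inductive/steric factors for backbone amide hydrogen exchange,
# log10 scale, D2O solvent. Transcription of the poly-DL-alanine-referenced
# compilation of Bai, Milne, Mayne & Englander (1993), Proteins 17:75-86,
# Table 2 (with the Connelly et al. 1993 treatment of ionizable side chains).
# lambda_* act on the amide of the residue itself; rho_* act on the amide of
# the following residue. Ionizable residues carry one row per protonation
# state; the calculator blends them by Henderson-Hasselbalch at the working pD.
# Table version: bai1993-d2o-v1
code,lambda_acid,rho_acid,lambda_base,rho_base
A,0.00,0.00,0.00,0.00
C,-0.54,-0.46,0.62,0.55
D-,0.90,0.58,0.10,-0.18
D0,-0.90,-0.12,0.69,0.60
E-,-0.90,0.31,-0.11,-0.15
E0,-0.60,-0.27,0.24,0.39
F,-0.52,-0.43,-0.24,0.06
G,-0.22,0.22,0.27,0.17
H+,-0.80,-0.51,0.80,0.83
H0,0.00,0.00,-0.10,0.14
I,-0.91,-0.59,-0.73,-0.23
K,-0.56,-0.29,-0.04,0.12
L,-0.57,-0.13,-0.58,-0.21
M,-0.64,-0.28,-0.01,0.11
N,-0.58,-0.13,0.49,0.32
P,0.00,-0.19,0.00,-0.24
Q,-0.47,-0.27,0.06,0.20
R,-0.59,-0.32,0.08,0.22
S,-0.44,-0.39,0.37,0.30
T,-0.79,-0.47,-0.07,0.20
V,-0.74,-0.30,-0.70,-0.14
W,-0.40,-0.44,-0.41,-0.11
Y,-0.41,-0.37,-0.27,0.05
NT,0.00,-1.32,0.00,1.62
CT0,0.96,0.00,-1.80,0.00
CT-,0.05,0.00,0.00,0.00
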