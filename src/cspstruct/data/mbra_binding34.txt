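# Ligand-binding residues of the reference moth CSP structure (MbraCSPA6,
# liganded form): every residue with a heavy atom within 5 A of the three
# bromo-dodecanol ligands, in reference numbering.
Y24
D25
I27
L29
I32
L39
Y42
V43
V46
E55
G56
E58
L59
H62
L63
A66
I67
G70
C71
C74
N77
Q78
G81
A82
V85
I86
L89
W97
L100
T101
D105
W110
R111
Y114
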