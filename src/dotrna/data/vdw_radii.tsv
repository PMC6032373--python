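# Heavy-atom van der Waals radii (Angstrom), NACCESS-compatible set
element	radius
C	1.87
N	1.65
O	1.40
S	1.85
P	1.90
H	1.00
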