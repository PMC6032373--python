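# AMBER-style Lennard-Jones parameters and representative partial charges
# for the heavy-atom types this pipeline handles. R* in Angstrom, eps* in
# kcal/mol, charge in electron units. Atom-name rows take precedence;
# element:X rows are united-atom fallbacks (charge applies only when the
# atom name itself is listed). Editable configuration, not a constant.
atom_type	rstar	epsstar	charge
N	1.8240	0.1700	-0.4157
CA	1.9080	0.1094	0.0337
C	1.9080	0.0860	0.5973
O	1.6612	0.2100	-0.5679
OXT	1.6612	0.2100	-0.8055
CB	1.9080	0.1094	-0.1000
P	2.1000	0.2000	1.1662
OP1	1.6612	0.2100	-0.7760
OP2	1.6612	0.2100	-0.7760
O5'	1.6837	0.1700	-0.4989
C1'	1.9080	0.1094	0.0394
N9	1.8240	0.1700	-0.0251
N1	1.8240	0.1700	-0.0339
element:C	1.9080	0.0860	0.0
element:N	1.8240	0.1700	0.0
element:O	1.6612	0.2100	0.0
element:S	2.0000	0.2500	0.0
element:P	2.1000	0.2000	0.0
element:H	0.6000	0.0157	0.0
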