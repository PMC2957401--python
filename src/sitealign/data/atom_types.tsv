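# Physico-chemical atom classes for protein heavy atoms, keyed by
# (residue name, atom name).  Classes: ACC = H-bond acceptor, DO = donor,
# AD = acceptor/donor, ALI = aliphatic, PI = aromatic.  A residue name of
# "*" applies to any residue (backbone atoms).  Atoms not listed here fall
# back to element-based rules in structure_io.assign_atom_properties.
# version: 1
resname	atomname	label
*	N	DO
*	O	ACC
*	OXT	ACC
*	C	ALI
*	CA	ALI
*	CB	ALI
ARG	CG	ALI
ARG	CD	ALI
ARG	NE	DO
ARG	CZ	ALI
ARG	NH1	DO
ARG	NH2	DO
ASN	CG	ALI
ASN	OD1	ACC
ASN	ND2	DO
ASP	CG	ALI
ASP	OD1	ACC
ASP	OD2	ACC
CYS	SG	ALI
GLN	CG	ALI
GLN	CD	ALI
GLN	OE1	ACC
GLN	NE2	DO
GLU	CG	ALI
GLU	CD	ALI
GLU	OE1	ACC
GLU	OE2	ACC
HIS	CG	PI
HIS	ND1	AD
HIS	CD2	PI
HIS	CE1	PI
HIS	NE2	AD
ILE	CG1	ALI
ILE	CG2	ALI
ILE	CD1	ALI
LEU	CG	ALI
LEU	CD1	ALI
LEU	CD2	ALI
LYS	CG	ALI
LYS	CD	ALI
LYS	CE	ALI
LYS	NZ	DO
MET	CG	ALI
MET	SD	ALI
MET	CE	ALI
PHE	CG	PI
PHE	CD1	PI
PHE	CD2	PI
PHE	CE1	PI
PHE	CE2	PI
PHE	CZ	PI
PRO	CG	ALI
PRO	CD	ALI
SER	OG	AD
THR	OG1	AD
THR	CG2	ALI
TRP	CG	PI
TRP	CD1	PI
TRP	CD2	PI
TRP	NE1	DO
TRP	CE2	PI
TRP	CE3	PI
TRP	CZ2	PI
TRP	CZ3	PI
TRP	CH2	PI
TYR	CG	PI
TYR	CD1	PI
TYR	CD2	PI
TYR	CE1	PI
TYR	CE2	PI
TYR	CZ	PI
TYR	OH	AD
VAL	CG1	ALI
VAL	CG2	ALI
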