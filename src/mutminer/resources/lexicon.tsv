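term	category	maps_to
alanine	amino_acid	A
arginine	amino_acid	R
asparagine	amino_acid	N
aspartic acid	amino_acid	D
aspartate	amino_acid	D
cysteine	amino_acid	C
glutamic acid	amino_acid	E
glutamate	amino_acid	E
glutamine	amino_acid	Q
glycine	amino_acid	G
histidine	amino_acid	H
isoleucine	amino_acid	I
leucine	amino_acid	L
lysine	amino_acid	K
methionine	amino_acid	M
phenylalanine	amino_acid	F
proline	amino_acid	P
serine	amino_acid	S
threonine	amino_acid	T
tryptophan	amino_acid	W
tyrosine	amino_acid	Y
valine	amino_acid	V
substituted	substitution_verb
replaced	substitution_verb
changed	substitution_verb
exchanged	substitution_verb
mutated	substitution_verb
converted	substitution_verb
substitution	substitution_noun
replacement	substitution_noun
change	substitution_noun
mutation	substitution_noun
exchange	substitution_noun
conversion	substitution_noun
codon	position_noun
residue	position_noun
position	position_noun
amino acid	position_noun
amber	nonsense_keyword	*
ochre	nonsense_keyword	*
opal	nonsense_keyword	*
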