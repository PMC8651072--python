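# Default pharmacophore rule table, version 1.
# One rule per line: SMARTS pattern, whitespace, label.
# An atom receives a label if it matches any pattern carrying that label;
# atoms may carry several labels. Lines starting with '#' are comments.
#
# Labels: Hydrophobic, Aromatic, Acceptor, Donor,
#         PositiveIonizable, NegativeIonizable

# Aromatic: any atom flagged aromatic by the perception model.
[a]	Aromatic

# Hydrophobic: uncharged carbon (aliphatic or aromatic) with no
# N/O/S/P neighbour, and halogens bound to carbon.
[C;+0;!$(C~[#7,#8,#15,#16])]	Hydrophobic
[c;+0;!$(c~[#7,#8,#15,#16])]	Hydrophobic
[F,Cl,Br,I;$(*[#6])]	Hydrophobic

# H-bond donor: N-H or O-H (neutral or cationic N-H), S-H.
[$([N;!H0;v3]),$([N;!H0;+1;v4]),$([n;H1;+0])]	Donor
[$([O;H1;+0]),$([S;H1;+0])]	Donor

# H-bond acceptor: neutral O (not in nitro etc.), anionic O,
# basic sp3/sp2 N not bonded to acyl/sulfonyl, aromatic n/o with lone pair.
[$([O;H1;v2;!$(O-*=[O,N,P,S])]),$([O;H0;v2]),$([O;-]),$([o;+0;!$([o]:n);!$([o]:c:n)])]	Acceptor
[$([N;v3;H0;+0;!$(N=*);!$(N-*=[O,N,P,S])]),$([N;v3;H1;+0;!$(N-*=[O,N,P,S]);!$(N-a)]),$([n;+0;H0;!$([n](:*)(:*):*:*:[#7])])]	Acceptor

# Positive ionizable: aliphatic amines (primary/secondary/tertiary,
# not amide/aniline-like), guanidinium/amidine carbon-nitrogens,
# and any formally cationic N.
[$([N;H2;+0][C;!$(C=*);!$(C#*)]),$([N;H1;+0]([C;!$(C=*);!$(C#*)])[C;!$(C=*);!$(C#*)]),$([N;H0;+0]([C;!$(C=*);!$(C#*)])([C;!$(C=*);!$(C#*)])[C;!$(C=*);!$(C#*)])]	PositiveIonizable
[$([N;+1]),$([n;+1])]	PositiveIonizable
[$([N;H1,H2;+0]C(=[N;+0,+1])[N;+0,+1]),$([N;+0,+1]=C([N;!H0])[N;+0,+1])]	PositiveIonizable

# Negative ionizable: carboxylic/sulfonic/phosphonic acid oxygens
# (protonated or deprotonated), tetrazole N-H.
[$([O;H1,-1][C,S,P]=O),$([O]=[C,S,P][O;H1,-1])]	NegativeIonizable
[$([nH]1nnnc1),$([n;-1]1nnnc1)]	NegativeIonizable
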