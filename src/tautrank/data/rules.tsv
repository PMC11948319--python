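# Prototropic tautomeric transformation rules (reaction SMIRKS).
# One record per rule: id <TAB> name <TAB> SMIRKS.
# Patterns are written with the migrating hydrogen mapped explicitly; the
# enumerator applies them to kekulized molecules with explicit hydrogens so
# the H and heavy-atom bookkeeping is exact.
ke13f	1,3 keto-enol shift (keto to enol)	[O:1]=[C:2][C;X4:3][H:4]>>[H:4][O:1][C:2]=[C:3]
ke13r	1,3 keto-enol shift (enol to keto)	[H:4][O;X2:1][C:2]=[C:3]>>[O:1]=[C:2][C:3][H:4]
am13f	1,3 amide/imidic acid (amide to imidic acid)	[O:1]=[C:2][#7:3][H:4]>>[H:4][O:1][C:2]=[#7:3]
am13r	1,3 amide/imidic acid (imidic acid to amide)	[H:4][O;X2:1][C:2]=[#7;X2:3]>>[O:1]=[C:2][#7:3][H:4]
ta13f	1,3 thioamide/thioimidic acid (forward)	[S:1]=[C:2][#7:3][H:4]>>[H:4][S:1][C:2]=[#7:3]
ta13r	1,3 thioamide/thioimidic acid (reverse)	[H:4][S;X2:1][C:2]=[#7;X2:3]>>[S:1]=[C:2][#7:3][H:4]
ie13f	1,3 imine/enamine (imine to enamine)	[#7;X2:1]=[C:2][C;X4:3][H:4]>>[H:4][#7:1][C:2]=[C:3]
ie13r	1,3 imine/enamine (enamine to imine)	[H:4][#7;X3:1][C:2]=[C:3]>>[#7:1]=[C:2][C:3][H:4]
no13f	1,3 nitroso/oxime (nitroso to oxime)	[O;X1:1]=[N;X2:2][C;X4:3][H:4]>>[H:4][O:1][N:2]=[C:3]
no13r	1,3 nitroso/oxime (oxime to nitroso)	[H:4][O;X2:1][N;X2:2]=[C:3]>>[O:1]=[N:2][C:3][H:4]
ad13	1,3 amidine shift	[#7;X2:1]=[C:2][#7:3][H:4]>>[H:4][#7:1][C:2]=[#7:3]
ke15f	1,5 keto-enol shift (keto to enol)	[O:1]=[C:2][C:3]=[C:4][C;X4:5][H:6]>>[H:6][O:1][C:2]=[C:3][C:4]=[C:5]
ke15r	1,5 keto-enol shift (enol to keto)	[H:6][O;X2:1][C:2]=[C:3][C:4]=[C:5]>>[O:1]=[C:2][C:3]=[C:4][C:5][H:6]
az15	1,5 aza keto-enol shift	[O:1]=[C:2][#7:3]=[C:4][#7:5][H:6]>>[H:6][O:1][C:2]=[#7:3][C:4]=[#7:5]
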