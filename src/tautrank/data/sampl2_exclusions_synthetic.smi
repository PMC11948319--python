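# Synthetic stand-in for the SAMPL2-challenge exclusion list.
# The curation step excludes any record whose pair members match an entry
# here by canonical SMILES.  These entries are representative heterocycles
# invented for tests; replace this file with the canonical SMILES of the
# real challenge molecules to reproduce a published curation.
O=c1cc[nH]c(=O)[nH]1	uracil-like
Cc1cc(=O)[nH]c(=O)[nH]1	methyluracil-like
O=c1[nH]cnc2[nH]cnc12	purinone-like
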