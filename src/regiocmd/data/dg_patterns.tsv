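smarts	dg_strength_kcal
[cH1]cC(N(C)A)=O	-2.7
[cH1]cC(N([C,c])[C,c])=O	-2.5
[cH1]cCN(C)C	-14.3
[cH1]c-C(=O)c	-1.7
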