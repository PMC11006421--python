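marker	gene
F4/80	Adgre1
Tim4	Timd4
CD206	Mrc1
CD169	Siglec1
CD106	Vcam1
CD115	Csf1r
Cx3cr1	Cx3cr1
Ly6C	Ly6c2
Ly6G	Ly6g
CD11b	Itgam
CD45	Ptprc
CD150	Slamf1
CD41	Itga2b
c-Kit	Kit
Ter119	Ly76
Clec4f	Clec4f
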