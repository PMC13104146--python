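pathway	ligand	receptor
MK	MDK	NCL
MK	MDK	SDC1
MK	MDK	SDC2
MK	MDK	PTPRZ1
MK	MDK	ITGA6,ITGB1
SPP1	SPP1	CD44
SPP1	SPP1	ITGAV,ITGB1
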