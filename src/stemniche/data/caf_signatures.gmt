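myCAF	myCAF	FAP	ACTA2	TAGLN	POSTN	MYL9
iCAF	iCAF	IL6	CXCL12	PDGFRA
apCAF	apCAF	HLA-DRA	CD74
vCAF	vCAF	NOTCH3	RGS5
mesCAF	mesCAF	MSLN	UPK3B
adipoCAF	adipoCAF	APOD	CFD
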