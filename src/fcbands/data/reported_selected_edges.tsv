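band	region_i	region_j
slow5	IPL.L	MTG.L
slow5	MFG.L	PCG.R
slow5	CUN.L	ORBmid.L
slow5	OLF.L	REC.L
slow5	ORBsupmed.L	PUT.L
slow5	PCG.R	PCL.R
slow5	CAL.L	CAL.R
slow5	LING.L	CAL.R
slow5	CAL.R	LING.R
slow4	CAL.L	PreCG.L
slow4	IFGoperc.R	SFGdor.R
slow4	IFGtriang.L	ORBsup.R
slow4	ORBinf.R	ORBsup.R
slow4	IFGoperc.R	OLF.R
slow4	ACG.R	OLF.R
slow4	ORBsupmed.R	PCUN.R
slow4	CAU.R	HIP.R
slow4	CAL.L	LING.L
slow4	LING.L	LING.R
slow4	IPL.L	TPOmid.L
slow4	TPOmid.L	SMG.R
slow4	CAU.L	PUT.L
slow4	HES.L	THA.L
wholeband	CAL.R	LING.L
wholeband	ORBinf.L	SFGdor.R
wholeband	HIP.R	IOG.R
wholeband	MTG.R	SFGdor.R
wholeband	MFG.R	SFGmed.L
wholeband	FFG.L	HES.L
wholeband	AMYG.R	IOG.R
wholeband	AMYG.L	IFGoperc.L
wholeband	LING.L	TPOsup.R
wholeband	IOG.R	PreCG.R
wholeband	IPL.L	TPOmid.L
wholeband	CAL.L	LING.L
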