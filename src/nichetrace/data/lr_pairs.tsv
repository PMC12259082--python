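ligand	receptor_subunits	pathway
Il18	Il18r1;Il18rap	IL18
Il18	Il18rap	IL18
Csf2	Csf2ra;Csf2rb	CSF
Csf2	Csf2rb	CSF
Csf1	Csf1r	CSF
Tgfb1	Tgfbr1;Tgfbr2	TGFb
Tgfb2	Tgfbr1;Tgfbr2	TGFb
Tgfb3	Tgfbr1;Tgfbr2	TGFb
Jag1	Notch1	NOTCH
Jag1	Notch2	NOTCH
Jag1	Notch3	NOTCH
Dll1	Notch1	NOTCH
Postn	Itgb3	POSTN
Postn	Itgb5	POSTN
Tnc	Itgb3	TENASCIN
Tnc	Sdc1	TENASCIN
Tnc	Sdc4	TENASCIN
Pdgfa	Pdgfra	PDGF
Pdgfb	Pdgfrb	PDGF
Pdgfb	Pdgfra	PDGF
Nrg1	Itgb3	NRG
Nrg1	Erbb3	NRG
Nrg1	Erbb4	NRG
Lif	Lifr;Il6st	LIF
Lif	Lifr	LIF
Il6	Il6ra;Il6st	IL6
Spp1	Cd44	SPP1
Spp1	Itgb3	SPP1
Il1b	Il1r1	IL1
Cxcl12	Cxcr4	CXCL
Fn1	Itgb1	FN1
Vegfa	Kdr	VEGF
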