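# kind	raw_name	canonical
# synonym: alternative spelling of a family name -> canonical display name
# rollup: subfamily or alias that rolls up to a parent family
synonym	bZIP	bZIP
synonym	Basic Leucine Zipper	bZIP
synonym	basic leucine zipper factors	bZIP
synonym	bHLH	bHLH
synonym	basic helix-loop-helix	bHLH
synonym	basic helix-loop-helix factors	bHLH
synonym	C2H2_ZF	C2H2_ZF
synonym	C2H2 zinc finger	C2H2_ZF
synonym	Zinc finger C2H2	C2H2_ZF
synonym	C2H2 zinc finger factors	C2H2_ZF
synonym	HMG	HMG
synonym	HMG box	HMG
synonym	High mobility group	HMG
synonym	T_box	T_box
synonym	T-box	T_box
synonym	Tbox	T_box
synonym	RHR	RHR
synonym	Rel homology region	RHR
synonym	Rel homology domain	RHR
synonym	bHSH	bHSH
synonym	basic helix-span-helix	bHSH
synonym	Tryptophan	Tryptophan
synonym	Tryptophan cluster	Tryptophan
synonym	homeodomain	homeodomain
synonym	Homeo domain	homeodomain
synonym	Homeobox	homeodomain
synonym	nuclear receptor	nuclear receptor
synonym	Nuclear hormone receptor	nuclear receptor
synonym	Nuclear receptors with C4 zinc fingers	nuclear receptor
synonym	forkhead	forkhead
synonym	Fork head	forkhead
synonym	Forkhead box	forkhead
synonym	FOX	forkhead
synonym	ETS	ETS
synonym	ETS domain	ETS
synonym	Tryptophan cluster factors	Tryptophan
rollup	E2A	bHLH
rollup	MYC	bHLH
rollup	CREB	bZIP
rollup	AP-2	bHSH
rollup	STAT	RHR
rollup	NF-kappaB	RHR
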