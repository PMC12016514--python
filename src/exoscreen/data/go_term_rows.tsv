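term	tf	p_adj_published	n_targeted	term_size	universe_size	genes
Small molecule biosynthetic process	Pdr1	0.009	90	346	7166	ILV5,ARG3,TDH3,GPP1,GCN4,OLE1,CPA1,HIS1,ERG5,MET6,LEU1,ERG25,LYS20,GLY1,PGK1
Carbohydrate metabolic process	Pdr1	0.053	90	270	7166	FKS1,KNH1,CIT2,PGK1,UTH1,TAL1,GAC1,TDH3,GPP1,SUN4,TYE7,CDC19
Carboxylic acid metabolic process	Pdr1	0.080	90	418	7166	OLE1,CPA1,CDC19,TYE7,HIS1,ILV5,ARG3,TDH3,GCN4,LYS20,GLY1,PGK1,CIT2,MET6,LEU1
Small molecule metabolic process	Yap1	2.61e-7	173	779	7166	TKL1,SOL3,HIS5,GND1,GCN4,PGK1,TAL1,GPP1,CPA2,ERG25,ILV5,ENO1,GPM1,YBR053C,ENO2,ARG3,BNA1,TPI1,ERG5,UGA3,HIS4,GID8,SLM5,ARG56,GLT1,ZWF1,MET6,LEU1,PDC1,URA2,DFR1,YDL124W,ADE12,YGK1,HSP31,ADH6,TRX1,CDC19,TYE7,OLE1,ADE2,CIT2,CPA1,TDH3,TDH2,ISA1,TDH1,MET17
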