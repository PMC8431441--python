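patient_id,outcome,nodal,n_stage,t_stage,stage,grade,er,pr,tils_percent
NDA01,ND,N0,N0,T1c,IA,G2,pos,pos,
NDA02,ND,N0,N0,T1c,IA,G2,pos,pos,
NDA03,ND,N0,N0,T1c,IA,G2,pos,pos,
NDA04,ND,N0,N0,T1c,IA,G2,pos,pos,
NDA05,ND,N0,N0,T1c,IA,G2,pos,neg,
NDA06,ND,N0,N0,T1c,IA,G3,pos,neg,
NDA07,ND,N0,N0,T1c,IA,G3,neg,neg,
NDA08,ND,N0,N0,T1c,IA,G3,neg,neg,
NDA09,ND,N0,N0,T1c,IA,G3,neg,neg,
NDA10,ND,N0,N0,T1c,IA,G3,neg,neg,
NDA11,ND,N0,N0,T1c,IA,G3,neg,neg,
NDA12,ND,N0,N0,T1c,IA,G3,neg,neg,
NDA13,ND,N0,N0,T2,IIA,G3,neg,neg,
NDA14,ND,N0,N0,T2,IIA,G3,neg,neg,
NDA15,ND,N0,N0,T2,IIA,G3,neg,neg,
NDA16,ND,N0,N0,T2,IIA,G3,neg,neg,
NDA17,ND,N0,N0,T2,IIA,G3,neg,neg,
NDA18,ND,N0,N0,T2,IIA,G3,neg,neg,
NDA19,ND,N0,N0,T2,IIA,G3,neg,neg,
NDB01,ND,N+,N1,T1c,IIA,G2,pos,pos,
NDB02,ND,N+,N1,T1c,IIA,G2,pos,pos,
NDB03,ND,N+,N1,T1c,IIA,G2,pos,pos,
NDB04,ND,N+,N1,T1c,IIB,G2,pos,neg,
NDB05,ND,N+,N1,T1c,IIB,G2,pos,neg,
NDB06,ND,N+,N1,T2,IIB,G2,pos,neg,
NDB07,ND,N+,N1,T2,IIB,G3,pos,neg,
NDB08,ND,N+,N1,T2,IIB,G3,neg,neg,
NDB09,ND,N+,N1,T2,IIB,G3,neg,neg,
NDB10,ND,N+,N1,T2,IIB,G3,neg,neg,
NDB11,ND,N+,N2,T2,IIB,G3,neg,neg,
NDB12,ND,N+,N2,T2,IIIA,G3,neg,neg,
NDB13,ND,N+,N2,T2,IIIA,G3,neg,neg,
NDB14,ND,N+,N3,T2,IIIC,G3,neg,neg,
NDB15,ND,N+,N3,T2,IIIC,G3,neg,neg,
NDB16,ND,N+,N3,T2,IIIC,G3,neg,neg,
NDB17,ND,N+,N3,T2,IIIC,G3,neg,neg,
NDB18,ND,N+,N3,T2,IIIC,G3,neg,neg,
NDB19,ND,N+,N3,T2,IIIC,G3,neg,neg,
PDA01,PD,N0,N0,T1c,IA,G2,pos,pos,
PDA02,PD,N0,N0,T1c,IA,G2,pos,pos,
PDA03,PD,N0,N0,T1c,IA,G2,pos,pos,
PDA04,PD,N0,N0,T2,IIA,G2,pos,pos,
PDA05,PD,N0,N0,T2,IIA,G3,neg,neg,
PDA06,PD,N0,N0,T2,IIA,G3,neg,neg,
PDA07,PD,N0,N0,T2,IIA,G3,neg,neg,
PDA08,PD,N0,N0,T2,IIB,G3,neg,neg,
PDB01,PD,N+,N1,T1c,IIA,G2,pos,pos,
PDB02,PD,N+,N1,T1c,IIA,G2,pos,pos,
PDB03,PD,N+,N1,T1c,IIB,G2,pos,pos,
PDB04,PD,N+,N1,T1c,IIB,G2,pos,pos,
PDB05,PD,N+,N2,T1c,IIB,G2,pos,pos,
PDB06,PD,N+,N2,T2,IIIA,G2,pos,pos,
PDB07,PD,N+,N2,T2,IIIA,G3,pos,pos,
PDB08,PD,N+,N2,T2,IIIA,G3,pos,pos,
PDB09,PD,N+,N2,T2,IIIA,G3,pos,neg,
PDB10,PD,N+,N2,T2,IIIA,G3,pos,neg,
PDB11,PD,N+,N2,T2,IIIA,G3,neg,neg,
PDB12,PD,N+,N3,T2,IIIC,G3,neg,neg,
PDB13,PD,N+,N3,T2,IIIC,G3,neg,neg,
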