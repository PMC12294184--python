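patient_id,family_id,gene,transcript,cdna_change,zygosity,protein_outcome,acmg_class,novel,conclusive,inheritance
P01,F1,ENAM,NM_031889.3,c.92T>C,het,p.Leu31Pro,likely_pathogenic,True,True,AD
P02,F2,ENAM,NM_031889.3,c.306G>A,het,p.Trp102Ter,likely_pathogenic,True,True,AD
P03,F3,ENAM,NM_031889.3,c.588+1del,het,p.?,pathogenic,False,True,AD
P04,F4,ENAM,NM_031889.3,c.1259_1260insAG,het,p.Pro422ValfsTer27,pathogenic,False,True,AD
P05,F5,ENAM,NM_031889.3,c.1259_1260insAG,hom,p.Pro422ValfsTer27,pathogenic,False,True,AR
P06,F5,ENAM,NM_031889.3,c.1259_1260insAG,hom,p.Pro422ValfsTer27,pathogenic,False,True,AR
P07,F6,ENAM,NM_031889.3,c.1259_1260insAG,hom,p.Pro422ValfsTer27,pathogenic,False,True,AR
P08,F7,ENAM,NM_031889.3,c.1259_1260insAG,hom,p.Pro422ValfsTer27,pathogenic,False,True,AR
P09,F8,ENAM,NM_031889.3,c.1259_1260insAG,hom,p.Pro422ValfsTer27,pathogenic,False,True,AR
P10,F9,AMELX,NM_182680.1,c.103-3T>C,het,p.?,likely_pathogenic,False,True,XLD
P11,F9,AMELX,NM_182680.1,c.103-3T>C,het,p.?,likely_pathogenic,False,True,XLD
P12,F10,AMELX,NM_182680.1,c.103-3T>C,het,p.?,likely_pathogenic,False,True,XLD
P12,F10,FAM83H,,c.2363G>A,het,p.Ser788Asn,benign,False,False,AD
P13,F11,AMELX,NM_182680.1,c.485delT,hemi,p.Phe162SerfsTer13,likely_pathogenic,True,True,XLD
P14,F12,MMP20,NM_004771.4,c.389C>T,hom,p.Thr130Ile,likely_pathogenic,False,True,AR
P15,F13,MMP20,NM_004771.4,c.389C>T,het,p.Thr130Ile,likely_pathogenic,False,True,AR
P15,F13,MMP20,NM_004771.4,c.446G>A,het,p.Trp149Ter,likely_pathogenic,True,True,AR
P16,F14,MMP20,NM_004771.4,c.540T>A,het,p.Tyr180Ter,likely_pathogenic,False,False,AR
P17,F15,MMP20,NM_004771.4,c.811G>T,het,p.Gly271Ter,likely_pathogenic,True,False,AR
P18,F15,MMP20,NM_004771.4,c.811G>T,het,p.Gly271Ter,likely_pathogenic,True,False,AR
P19,F16,MMP20,NM_004771.4,c.811G>T,het,p.Gly271Ter,likely_pathogenic,True,False,AR
P20,F17,LAMB3,,c.-132T>C,het,,vus,True,False,AD
P21,F18,FAM83H,,c.1669G>T,het,p.Gly557Cys,benign,False,False,AD
P22,F18,FAM83H,,c.1669G>T,het,p.Gly557Cys,benign,False,False,AD
P23,F19,,,,,,,False,False,
P24,F20,,,,,,,False,False,
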