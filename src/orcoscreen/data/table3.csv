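id,name,smiles,isomer_mixture,chemical_class,pharmacophore_hit,ic50_uM,mechanism
50,Appendix VOC 50,,0,uncharacterized,0,,inactive
51,Appendix VOC 51,,0,uncharacterized,0,,inactive
52,Appendix VOC 52,,0,uncharacterized,0,,inactive
53,2-Nonanone,CCCCCCCC(C)=O,0,ketone,1,,inactive
54,(Z)-3-Nonen-1-ol,CCCCC/C=C\CCO,0,aliphatic alcohol,1,48.9,orthosteric
55,Appendix VOC 55,,0,uncharacterized,0,,inactive
56,Appendix VOC 56,,0,uncharacterized,0,,inactive
57,Pulegone,CC1CCC(=C(C)C)C(=O)C1,0,monoterpene ketone,1,,inactive
58,Appendix VOC 58,,0,uncharacterized,0,,inactive
59,Limonene oxide (cis/trans mix),CC12CCC(CC1O2)C(=C)C,1,monoterpene epoxide,1,,inactive
60,"(2E,4E)-Decadienal",CCCCC/C=C/C=C/C=O,0,fatty aldehyde,1,66.7,orthosteric
61,Appendix VOC 61,,0,uncharacterized,0,,inactive
62,alpha-Pinene oxide,CC12OC1CC1CC2C1(C)C,0,monoterpene epoxide,0,52,allosteric
63,Appendix VOC 63,,0,uncharacterized,0,,inactive
64,Borneol,CC1(C)C2CCC1(C)C(O)C2,0,monoterpene alcohol,0,86.5,allosteric
65,p-Menth-1-en-9-ol,CC1=CCC(CC1)C(C)CO,0,monoterpene alcohol,1,,inactive
66,2-Methylquinoline,Cc1ccc2ccccc2n1,0,quinoline,0,115,allosteric
67,Appendix VOC 67,,0,uncharacterized,0,,inactive
68,cis-Jasmone,CC/C=C\CC1=C(C)CCC1=O,0,terpenoid,1,,inactive
69,Appendix VOC 69,,0,uncharacterized,0,,inactive
70,Appendix VOC 70,,0,uncharacterized,0,,inactive
71,gamma-Undecalactone,CCCCCCCC1CCC(=O)O1,0,lactone,1,,inactive
72,2-Tridecanone,CCCCCCCCCCCC(C)=O,0,ketone,1,,inactive
73,Appendix VOC 73,,0,uncharacterized,0,,inactive
74,Bisabolene (mix of isomers),CC(C)=CCCC(=C)C1CCC(C)=CC1,1,sesquiterpene,0,47.7,orthosteric
75,Aromadendrene,CC1CCC2C1C1C(C1(C)C)CCC2=C,0,sesquiterpene,0,26.2,allosteric
76,Appendix VOC 76,,0,uncharacterized,0,,inactive
77,alpha-Bisabolol,CC1=CCC(CC1)C(C)(O)CCC=C(C)C,0,sesquiterpene alcohol,1,47,orthosteric
78,1-Hexadecanol,CCCCCCCCCCCCCCCCO,0,fatty alcohol,1,,inactive
79,Phytol,CC(C)CCCC(C)CCCC(C)CCC/C(C)=C/CO,0,terpenoid,1,,inactive
80,Appendix VOC 80,,0,uncharacterized,0,,inactive
81,(Z)-Octadec-11-ene nitrile,CCCCCC/C=C\CCCCCCCCCC#N,0,fatty nitrile,1,,inactive
82,Appendix VOC 82,,0,uncharacterized,0,,inactive
83,13-Methyltetradec-3-ene nitrile,N#CC/C=C/CCCCCCCCC(C)C,0,fatty nitrile,1,25,orthosteric
84,"(9Z,12Z,15S)-Octadeca-9,12-dien-15-olide",O=C1CCCCCCC/C=C\C/C=C\CC(CCC)O1,0,macrocyclic unsaturated lactone,1,,inactive
85,N-(3-Methylbutyryl)-O-(2-methylpropionyl)-L-serine methyl ester,COC(=O)C(COC(=O)C(C)C)NC(=O)CC(C)C,0,diester amide,1,,inactive
86,Appendix VOC 86,,0,uncharacterized,0,,inactive
87,Appendix VOC 87,,0,uncharacterized,0,,inactive
88,Ethyl (E/Z)-2-(cyclohex-2-en-1-ylidene) acetate (mix of isomers),CCOC(=O)C=C1CCCC=C1,1,ester,1,195.7,orthosteric
89,7-Tetradecynoic acid,CCCCCCC#CCCCCCC(O)=O,0,unsaturated fatty acid,1,,inactive
90,Appendix VOC 90,,0,uncharacterized,0,,inactive
91,Appendix VOC 91,,0,uncharacterized,0,,inactive
92,Appendix VOC 92,,0,uncharacterized,0,,inactive
93,N-Phenylethyl-2-methyl propionic acid amide,CC(C)C(=O)NCCc1ccccc1,0,peptide,1,,inactive
94,(R)-2-Heptyl acetate,CCCCC[C@@H](C)OC(C)=O,0,ester,1,,inactive
95,2-Pentyl 2-methylbutanoate,CCC(C)C(=O)OC(C)CCC,0,ester,1,,inactive
96,13-Methyl tetradecane-1-ol,CC(C)CCCCCCCCCCCCO,0,fatty alcohol,1,,inactive
98,(E)-3-Methyl-2-(3-methylbutyliden)-4-butanolide,CC(C)C=C1C(C)COC1=O,0,lactone,1,43.2,orthosteric
99,"(4R,6R,8R)-Trimethyldecan-2-one",CC(=O)CC(C)CC(C)CC(C)CC,0,ketone,1,57,orthosteric
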