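id,name,smiles,isomer_mixture,chemical_class,active_orthosteric
II,Isopropyl cinnamate,CC(C)OC(=O)/C=C/c1ccccc1,0,cinnamate ester,1
IV,Ethyl cinnamate,CCOC(=O)/C=C/c1ccccc1,0,cinnamate ester,1
4,Linalyl acetate,CC(=O)OC(C)(C=C)CCC=C(C)C,0,monoterpene ester,1
39,"2,4-Octadienal",CCC/C=C/C=C/C=O,0,fatty aldehyde,1
33,2-Heptanone,CCCCCC(C)=O,0,ketone,0
40,6-Methyl-5-hepten-2-one,CC(C)=CCCC(C)=O,0,ketone,0
42,4-Octanone,CCCC(=O)CCCC,0,ketone,0
43,2-Octanone,CCCCCCC(C)=O,0,ketone,0
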