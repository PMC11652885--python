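id,name,smiles,isomer_mixture,chemical_class,antagonist_type
I,Carvacrol,Cc1ccc(C(C)C)cc1O,0,monoterpene alcohol,allosteric
II,Isopropyl cinnamate,CC(C)OC(=O)/C=C/c1ccccc1,0,cinnamate ester,orthosteric
III,Cumin alcohol,CC(C)c1ccc(CO)cc1,0,monoterpene alcohol,allosteric
IV,Ethyl cinnamate,CCOC(=O)/C=C/c1ccccc1,0,cinnamate ester,orthosteric
4,Linalyl acetate,CC(=O)OC(C)(C=C)CCC=C(C)C,0,monoterpene ester,orthosteric
39,"2,4-Octadienal",CCC/C=C/C=C/C=O,0,fatty aldehyde,orthosteric
45,(1S)-3-Carene,CC1=CCC2CC1C2(C)C,0,monoterpene,allosteric
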