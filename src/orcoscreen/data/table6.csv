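id,name,smiles,isomer_mixture,chemical_class,retained,response_pct
5284507,Nerolidol,CC(C)=CCCC(C)=CCCC(C)(O)C=C,0,sesquiterpene alcohol,1,51
31289,Nonanal,CCCCCCCCC=O,0,fatty aldehyde,1,65
637566,Geraniol,CC(C)=CCC/C(C)=C/CO,0,acyclic monoterpene alcohol,1,43
638011,Citral,CC(C)=CCC/C(C)=C/C=O,0,monoterpene aldehyde,1,69
8294,Linalyl acetate,CC(=O)OC(C)(C=C)CCC=C(C)C,0,monoterpene ester,1,59
7439,Carvone,CC(=C)C1CCC(C)=CC1=O,0,monoterpene ketone,0,71
1549026,Geranyl acetate,CC(C)=CCC/C(C)=C/COC(C)=O,0,monoterpene ester,0,67
1549778,Geranyl acetone,CC(=O)CC/C=C(C)/CCC=C(C)C,0,monoterpene ketone,0,92
379,Octanoic acid,CCCCCCCC(O)=O,0,fatty acid,0,81
6549,Linalool,CC(C)=CCCC(C)(O)C=C,0,monoterpene alcohol,0,98
17100,alpha-Terpineol,CC1=CCC(CC1)C(C)(C)O,0,monoterpene alcohol,0,100
31253,Myrcene,CC(C)=CCCC(=C)C=C,0,monoterpene,0,71
8892,Hexanoic acid,CCCCCC(O)=O,0,fatty acid,0,59
14525,Fenchone,CC1(C)C2CCC(C)(C2)C1=O,0,monoterpene ketone,0,67
22311,Limonene,CC1=CCC(CC1)C(=C)C,0,monoterpene,0,82
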