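id,name,smiles,isomer_mixture,chemical_class,pharmacophore_hit,ic50_uM
62,alpha-Pinene oxide,CC12OC1CC1CC2C1(C)C,0,monoterpene epoxide,0,52
64,Borneol,CC1(C)C2CCC1(C)C(O)C2,0,monoterpene alcohol,0,86.5
66,2-Methylquinoline,Cc1ccc2ccccc2n1,0,quinoline,0,115
75,Aromadendrene,CC1CCC2C1C1C(C1(C)C)CCC2=C,0,sesquiterpene,0,26.2
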