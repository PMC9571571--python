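name,smiles,clogp,solubility,mol_weight,tpsa,drug_likeness,drug_score,bbb,violations,mutagenicity,tumorigenicity,irritant,reproductive_effective,smiles_inconsistent
Acebutolol,O=C(N)Cc1ccc(cc1)OCC(O)CNC(C)C,1.7,-3.5,336.0,87.66,4.91,0.83,BBB-,0,No,No,No,No,true
beta-D-fructofuranose,C(C1C(C(C(O1)(CO)O)O)O)O,-2.7,0.38,180,110,-2.56,0.32,BBB-,0,No,No,No,Yes,
Elatin (flavonoid),CC1C(C(C(C(O1)C2=C3C(=C(C(=C2O)C4C(C(C(C(O4)CO)O)O)O)O)C(=O)C=C(O3)C5=CC(=C(C=C5)O)O)O)O)O,-1.91,-1.89,594,267.2,0.42,0.14,BBB-,3,Yes,Yes,No,No,
Coumarin,O=C1C=Cc2ccccc2O1,1.5,-2.37,146,26,-1.83,0.12,BBB+,0,Yes,Yes,No,Yes,
resveratrol,Oc1ccc(cc1)C=Cc1cc(O)cc(c1)O,2.83,-2.86,228.0,60.69,-3.25,0.27,BBB+,0,No,No,No,Yes,
Glycyrrhetinic acid,CC1(C2CCC3(C(C2(CCC1O)C)C(=O)C=C4C3(CCC5(C4CC(CC5)(C)C(=O)O)C)C)C)C,5.36,-5.78,470,74.6,-2.36,0.2,BBB-,1,No,No,No,No,
Glycyrrhizin,CC1(C2CCC3(C(C2(CCC1OC4C(C(C(C(O4)C(=O)O)O)O)OC5C(C(C(C(O5)C(=O)O)O)O)O)C)C(=O)C=C6C3(CCC7(C6CC(CC7)(C)C(=O)O)C)C)C)C.N.N.N,0.39,-5.14,822,267.0,-4.29,0.19,BBB-,3,No,No,No,No,
Amygdalin,C1=CC=C(C=C1)C(C#N)OC2C(C(C(C(O2)COC3C(C(C(C(O3)CO)O)O)O)O)O)O,-3.08,-1.12,457,202.3,-8.7,0.09,BBB-,2,Yes,No,Yes,Yes,
Porphyrin,C1=CC2=CC3=CC=C(N3)C=C4C=CC(=N4)C=C5C=CC(=N5)C=C1N2,2.05,-4.34,310.0,52.54,0.97,0.67,BBB+,1,No,No,No,No,
Bicalutamide,CC(CS(=O)(=O)C1=CC=C(C=C1)F)(C(=O)NC2=CC(=C(C=C2)C#N)C(F)(F)F)O,2.14,-5.08,430,115,-11,0.24,BBB+,0,No,No,No,No,
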