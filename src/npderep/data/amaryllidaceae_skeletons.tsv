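# Eight ring skeletons commonly found in Amaryllidaceae alkaloids, following
# the standard skeleton nomenclature of the Amaryllidaceae-alkaloid literature.
# mode scaffold: the SMILES is reduced to its Murcko scaffold and matched with
# generic bonds, so hydroxylated / unsaturated variants of a skeleton still hit.
# mode smarts:   the pattern is compiled directly as SMARTS (used for the acyclic
# norbelladine linker, which must NOT match ring-embedded C-C-N-C paths).
# columns: name	mode	pattern	comment
crinane	scaffold	C1CCC2C3(CCN2Cc2ccccc23)C1	5,10b-ethanophenanthridine core (crinine, vittatine, haemanthamine type)
lycorane	scaffold	C1=C2CCN3Cc4ccccc4C(CC1)C23	pyrrolo[de]phenanthridine core (lycorine type)
galanthamine	scaffold	C1CC23C=CC(O)CC2Oc2cccc(CN1)c23	dibenzofuran-derived core with azepine ring (galanthamine type)
tazettine	scaffold	CN1Cc2ccccc2C23C=CC(OC)CC2C1(O)OC3	2-benzopyrano[3,4-c]indole core (tazettine, pretazettine type)
homolycorine	scaffold	CN1CCC2C=CC3OC(=O)c4ccccc4C3C12	2-benzopyranone-fused hydroindole core (homolycorine, albomaculine type)
montanine	scaffold	C1C=C2C3CC1CCN3Cc1ccccc12	5,11-methanomorphanthridine core (montanine type)
norbelladine	smarts	c1ccc(cc1)[CX4;!R][CX4;!R][NX3;!R][CX4;!R]c1ccccc1	open-chain N-benzyl phenethylamine precursor (norbelladine type)
phenanthridone	scaffold	O=C1Nc2ccccc2-c2ccccc21	phenanthridin-6(5H)-one core (narciclasine, lycoricidine type)
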