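# Hierarchical chemical-class catalog (CL1 style), four levels of dotted IDs.
# Level-1 split: 01 = derived from primary metabolites, 02 = secondary metabolites.
# A node is assigned when any of its patterns matches; ancestors of an assigned
# node are always assigned too.  Branch nodes may have no pattern of their own.
# pattern modes: smarts   = pattern text compiled as SMARTS (SMILES accepted),
#                scaffold = SMILES reduced to its Murcko scaffold and matched
#                           with generic (any-order) bonds, for ring skeletons
#                           that tolerate unsaturation/oxidation variants.
# columns: class_id	label	parent_id	mode	patterns (pipe-separated)
01	primary-metabolite derived
01-01	sugars	01
01-01-14	hexopyranoses	01-01	smarts	OCC1OC(O)C(O)C(O)C1O
01-01-14-005	alpha-D-glucopyranose	01-01-14	smarts	OC[C@H]1O[C@H](O)[C@H](O)[C@@H](O)[C@@H]1O
01-01-14-006	beta-D-glucopyranose	01-01-14	smarts	OC[C@H]1O[C@@H](O)[C@H](O)[C@@H](O)[C@@H]1O
01-02	alpha-amino acids	01	smarts	[NX3;H2,H1][CX4H]C(=O)[OX2H1,OX1-]
02	secondary metabolites
02-01	alkaloids	02
02-01-01	Amaryllidaceae alkaloids	02-01
02-01-01-001	crinane skeleton	02-01-01	scaffold	C1CCC2C3(CCN2Cc2ccccc23)C1
02-01-01-002	lycorane skeleton	02-01-01	scaffold	C1=C2CCN3Cc4ccccc4C(CC1)C23
02-01-01-003	galanthamine skeleton	02-01-01	scaffold	C1CC23C=CC(O)CC2Oc2cccc(CN1)c23
02-01-01-004	tazettine skeleton	02-01-01	scaffold	CN1Cc2ccccc2C23C=CC(OC)CC2C1(O)OC3
02-01-01-005	homolycorine skeleton	02-01-01	scaffold	CN1CCC2C=CC3OC(=O)c4ccccc4C3C12
02-01-01-006	montanine skeleton	02-01-01	scaffold	C1C=C2C3CC1CCN3Cc1ccccc12
02-01-01-007	norbelladine skeleton	02-01-01	smarts	c1ccc(cc1)[CX4;!R][CX4;!R][NX3;!R][CX4;!R]c1ccccc1
02-01-01-008	phenanthridone skeleton	02-01-01	scaffold	O=C1Nc2ccccc2-c2ccccc21
02-02	terpenes	02
02-02-01	monoterpenes	02-02
02-02-01-001	menthane skeleton	02-02-01	smarts	CC1CCC(C(C)C)CC1
02-03	phenolics	02
02-03-01	flavonoids	02-03
02-03-01-001	flavone core	02-03-01	smarts	O=c1ccoc2ccccc12
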