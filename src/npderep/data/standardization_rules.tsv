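# Tautomer / functional-group standardization rules, applied in file order.
# Each rule is a reaction SMARTS (SMIRKS) rewriting an unlikely form produced
# by InChI decoding into the conventional one.  Tautomers share an InChI, so
# these rewrites never change the InChI of a record.
# columns: rule_id	smirks	comment
iminol_to_amide	[C!$(C=C):1]([OX2H1:2])=[NX2:3]>>[C:1](=[O:2])[N:3]	aliphatic iminols decoded from InChI are rewritten to the amide form
nitroso_to_oxime	[CX4;!H0:1][NX2:2]=[OX1:3]>>[C:1]=[N:2][OX2:3]	C-nitroso with an alpha H normalized to the oxime
enol_dione_to_diketone	[CX3:1]([OX2H1:2])=[CX3;!H0:3][CX3:4]=[OX1:5]>>[C:1](=[O:2])[C:3][C:4]=[O:5]	enol of a 1,3-dione rewritten to the diketo form
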