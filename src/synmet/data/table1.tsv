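organism	B	R	R_A	N
Buchnera aphidicola	43	205	183	2
Helicobacter pylori	52	394	298	35
Staphylococcus aureus	58	534	286	41
Bacillus subtilis	59	769	327	97
Methanosarcina barkeri	63	531	352	6
Escherichia coli	67	1396	388	175
Mycobacterium tuberculosis	93	836	408	39
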