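# Default per-unit triplex binding energies, kcal/mol.
# SYNTHETIC default values: these are package-supplied stand-ins chosen to be
# distinct and negative (binding-stabilizing), with the G-keyed motifs
# stronger than the A-keyed ones. They are parameters, not computed
# quantities; replace with your own table (same columns) for absolute-energy
# work. Relative machinery (summation, dominance ranking) does not depend on
# the particular values.
mode	purine_base	third_base	energy_kcal_mol
hoogsteen	A	U	-4.9
hoogsteen	G	C	-7.3
reverse_hoogsteen	A	A	-5.6
reverse_hoogsteen	G	G	-8.1
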