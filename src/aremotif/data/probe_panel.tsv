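name	sequence	are_class	reported_binding	provenance
Ikzf2 ARE1	UUUACUAGGGCUAUUUAUUCCACUAUUU	7mer	bind	inferred
Ikzf2 ARE2	AAGGAUAUUUAUUUCUGAAUGAGGUAAAUAAGUU	7mer	bind	inferred
Ikzf2 ARE3	UUAUUCAUAUUUAUAUGUAGUGUGUUCU	7mer	bind	inferred
Mpl	GUGGGGUCUUGCUGUCAUCUAUUUAUUUGAUCUCUC	7mer	bind	inferred
Mpl mut	GUGGGGUCUUGCUGUCAUAUAUUUAUUUGAUCUCUC	7mer	bind	inferred
Irf8	AAGGAGUGCUAGUGUCCAAAUAUUUAUUUUUGUAUUCUCU	7mer	bind	inferred
Nfix	UGGGCUUUAUUUAUUGAGAAUCUAGUU	7mer	bind	inferred
Elavl2 ARE1	UACAUGUAUAUAUUUAAAAAAAAAAAUAAGG	5mer_only	no_bind	stated_in_text
Elavl2 ARE2	UGUUGUCCUGAGGACUUGAAUUUACAGUGCAUCA	5mer_only	no_bind	stated_in_text
Elavl2 ARE3	UGAGCUCUUGUCCUCAGUCCAUUUAUAUAUGA	5mer_only	no_bind	stated_in_text
Elavl2 ARE4	UGUAAGGCUGGUAUUUAUUUGAAGUUGUACA	7mer	bind	stated_in_text
Elavl2 ARE5	CAAACAGUAUUUAUUUUGUAAUUCUGAUUUG	7mer	bind	stated_in_text
Elavl2 ARE6	UUUGAAGUUUACAUUUUUAUUUAUGAAGUUACAAA	7mer	bind	stated_in_text
Apol11b	AAUGUCAGAAAUAUUUAUUUUCUUGAAGA	7mer	bind	inferred
Fgf23	GUUAAUCUGAUUUAAAGACCCCAACAGGUAAAC	5mer_only	no_bind	stated_in_text
Gm-csf	UUUAUUUAUUUAUUUAAGUUCAUAUUCCAU	7mer	bind	stated_in_text
Tnf-alpha	UGAUUAUUUAUUAUUUAUUUAUUAUUUAUUUAUUUACAGAUGAAUGUAUUUAUUUGGG	7mer	bind	stated_in_text
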