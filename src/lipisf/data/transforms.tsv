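name	polarity	kind	delta_gain	delta_loss	charge_carrier	plausible
[M+H]+	positive	adduct	-	-	protonation	true
[M+Na]+	positive	adduct	Na	-	cation_exchange	true
[M+K]+	positive	adduct	K	-	cation_exchange	true
[M-H]-	negative	adduct	-	-	deprotonation	true
[M+Cl]-	negative	adduct	Cl	-	anion_attachment	true
[M+Na-2H]-	negative	adduct	Na	H2	cation_exchange	true
[M-OH]-	negative	adduct	-	HO	neutral_loss_anion	true
[M-CH3]-	negative	adduct	-	CH3	neutral_loss_anion	true
[M-CH3-NH2]-	negative	fragment	-	CH5N	neutral_loss_anion	true
[M-H-C4H10O5]-	negative	fragment	-	C4H10O5	deprotonation	true
[M-2H2O-NH2]-	negative	fragment	-	H6NO2	neutral_loss_anion	true
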