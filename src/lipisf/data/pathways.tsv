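class	polarity	transform_name
PC	positive	[M+H]+
PC	positive	[M+Na]+
PC	positive	[M+K]+
PE	positive	[M+H]+
PE	positive	[M+Na]+
PE	positive	[M+K]+
PS	positive	[M+H]+
PS	positive	[M+Na]+
PS	positive	[M+K]+
PA	positive	[M+H]+
PA	positive	[M+Na]+
PA	positive	[M+K]+
PG	positive	[M+H]+
PG	positive	[M+Na]+
PG	positive	[M+K]+
PI	positive	[M+H]+
PI	positive	[M+Na]+
PI	positive	[M+K]+
SM	positive	[M+H]+
SM	positive	[M+Na]+
SM	positive	[M+K]+
PC	negative	[M-H]-
PC	negative	[M+Cl]-
PC	negative	[M-CH3]-
PC	negative	[M-CH3-NH2]-
PE	negative	[M-H]-
PE	negative	[M+Cl]-
PE	negative	[M+Na-2H]-
PE	negative	[M-2H2O-NH2]-
PS	negative	[M-H]-
PS	negative	[M+Na-2H]-
PS	negative	[M-2H2O-NH2]-
PA	negative	[M-H]-
PA	negative	[M+Na-2H]-
PA	negative	[M-OH]-
PG	negative	[M-H]-
PG	negative	[M+Na-2H]-
PG	negative	[M-OH]-
PI	negative	[M-H]-
PI	negative	[M-OH]-
PI	negative	[M-CH3]-
PI	negative	[M+Na-2H]-
PI	negative	[M-CH3-NH2]-
PI	negative	[M-H-C4H10O5]-
PI	negative	[M-2H2O-NH2]-
SM	negative	[M-H]-
SM	negative	[M+Cl]-
SM	negative	[M-CH3]-
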