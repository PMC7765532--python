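train	test	class	mean	sd
SF	SF	nontarget	0.822	0.059
SF	SF	target	0.803	0.056
SF	SF	total	0.812	0.057
CF	SF	nontarget	0.817	0.060
CF	SF	target	0.412	0.107
CF	SF	total	0.619	0.060
SF	CF	nontarget	0.753	0.058
SF	CF	target	0.551	0.099
SF	CF	total	0.652	0.066
CF	CF	nontarget	0.878	0.060
CF	CF	target	0.848	0.056
CF	CF	total	0.863	0.057
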