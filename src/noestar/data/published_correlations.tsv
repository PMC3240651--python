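# Reported correlation magnitudes and sample sizes for linear regressions of
# NHNOE* versus disorder probability in six mammalian p53TAD homologues
# (three predictors each). printed_p is the reported two-tailed p-value;
# values prefixed '<' are printed upper bounds.
species	predictor	n	r	printed_p
Human	IUPred	58	0.55	0.000008
Human	VL-XT	58	0.54	0.000012
Human	VSL2B	58	0.42	0.00103
Dog	IUPred	60	0.44	0.000435
Dog	VL-XT	60	0.65	<0.000001
Dog	VSL2B	60	0.49	0.000071
Mouse	IUPred	60	0.65	<0.000001
Mouse	VL-XT	60	0.58	0.000001
Mouse	VSL2B	60	0.51	0.000031
Cow	IUPred	59	0.59	0.000001
Cow	VL-XT	59	0.66	<0.000001
Cow	VSL2B	59	0.62	<0.000001
Guinea Pig	IUPred	61	0.58	0.000001
Guinea Pig	VL-XT	61	0.53	0.000014
Guinea Pig	VSL2B	61	0.71	<0.000001
Rabbit	IUPred	62	0.43	0.000524
Rabbit	VL-XT	62	0.43	0.000515
Rabbit	VSL2B	62	0.48	0.000065
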