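trait	disease_class	cases	controls	subtype_cases
breast	cancer	122977	105974	er_positive=69501;er_negative=21468
ovarian	cancer	25509	40941	hgsoc=13037
prostate	cancer	79148	61106	.
endometrial	cancer	12906	108979	.
crohns_disease	autoimmune	4474	9500	.
ulcerative_colitis	autoimmune	4173	9500	.
rheumatoid_arthritis	autoimmune	29880	73758	.
systemic_lupus_erythematosus	autoimmune	7219	15991	.
hashimoto_thyroiditis	autoimmune	30234	725172	.
multiple_sclerosis	autoimmune	14498	24091	.
type_1_diabetes	autoimmune	22153	37374	.
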