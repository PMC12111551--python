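analysis	n_leads
breast	80
breast_er_positive	83
breast_er_negative	35
ovarian	27
ovarian_hgsoc	20
prostate	101
endometrial	52
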