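body_muscle	81
death	67
germ	2
hypodermis	131
intestine	20
nervous_system	195
pharynx	112
unknown	30
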