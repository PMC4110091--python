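blast	5
death	131
epithelial	262
germ	2
gland	13
intestinal	20
muscle	153
neural_structural	46
neuron	305
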