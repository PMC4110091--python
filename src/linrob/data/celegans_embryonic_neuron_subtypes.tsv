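blast	39
death	113
epithelial	93
germ	2
gland	13
intestinal	20
muscle	123
neural_structural	46
excretory_canal_neuron	2
interneuron	95
motor_neuron	45
polymodal_neuron	26
sensory_neuron	54
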