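endoderm	12
epidermis	50
mesenchyme	6
muscle	10
nervous_system	16
notochord	10
undifferentiated	6
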