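gene	obs_syn	exp_syn	obs_mis	exp_mis	obs_lof	exp_lof
NPC1	314	290.7	637	719.4	21	62.2
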