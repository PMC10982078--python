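group_1	group_2	kind	mean_pct
Italy	Italy	within	3.0
Rest of the World	Rest of the World	within	1.1
Outgroup	Outgroup	within	36.5
Italy	Rest of the World	between	22.4
Italy	Outgroup	between	55.8
Outgroup	Rest of the World	between	55.9
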