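genome2	782	989
genome2	3054	3210
genome2	5465	5684
genome2	6776	7031
genome2	7751	8141
genome2	9669	9939
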