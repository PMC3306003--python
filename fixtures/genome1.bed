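genome1	1266	1554
genome1	2476	2845
genome1	7881	8316
genome1	9420	9549
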