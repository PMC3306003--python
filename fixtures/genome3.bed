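genome3	335	482
genome3	949	1126
genome3	3150	3348
genome3	4207	4387
genome3	5655	6039
genome3	6372	6780
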