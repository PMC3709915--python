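	AA	AB	BB	XX
AA	95023653	33442	4430	39074
AB	41850	2363664	3969	3300
BB	3606	4646	496897	586
XX	89391	2930	706	926
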