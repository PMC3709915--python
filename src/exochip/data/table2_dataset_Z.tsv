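	AA	AB	BB	XX
AA	94964611	115849	4394	15745
AB	41864	2365462	5137	320
BB	3557	5635	496351	192
XX	89480	2996	714	763
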