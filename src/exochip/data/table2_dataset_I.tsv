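	AA	AB	BB	XX
AA	94878501	33679	4467	183952
AB	41395	2350644	4777	15967
BB	3658	4642	495626	1809
XX	89104	2905	711	1233
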