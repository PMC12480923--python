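id	age	sex	mt_s01	mt_s02
HP01	24	F	70	70
HP02	27	F	67	72
HP03	24	F	75	75
HP04	34	M	76	76
HP05	23	F	72	72
HP06	33	M	72	72
HP07	19	F	68	68
HP08	28	F	70	70
HP09	18	F	76	76
HP10	37	M	74	74
HP11	34	F	76	76
HP12	28	F	56	56
HP13	25	M	70	70
HP14	22	F	56	56
HP15	23	M	54	54
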