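genome	orfs	cytochromes	multiheme	hemes_per_cytochrome
G. bemidjiensis	4018	73	65	7.6
G. lovleyi	3685	61	46	4.8
G. metallireducens	3532	76	66	7.3
G. strain FRC-32	3396	68	58	9.6
G. sulfurreducens	3446	89	78	7.5
G. uraniireducens	4357	104	91	9.3
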