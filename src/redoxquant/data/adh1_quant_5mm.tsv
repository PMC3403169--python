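accession	sequence	start	end	confidence	area_114	err_114	area_116	err_116	area_118	err_118	area_121	err_121
ADH1_SYN	YSGVCHTDLHAWHGDWPLPVK	40	60	0.99	1000	0	478	143	467	180	258	195
ADH1_SYN	CCSDVFNQVVK	277	287	0.99	1000	0	2293	1041	397	150	346	293
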