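name	older_Ga	younger_Ga
Hadean	4.60	4.00
Eoarchean	4.00	3.60
Paleoarchean	3.60	3.20
Mesoarchean	3.20	2.80
Neoarchean	2.80	2.50
Paleoproterozoic	2.50	1.60
Mesoproterozoic	1.60	1.00
Neoproterozoic	1.00	0.538
Paleozoic	0.538	0.252
Mesozoic	0.252	0.066
Cenozoic	0.066	0.00
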