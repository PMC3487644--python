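Spaethiella sp.	0	1	1	0	0	N	0	1	0	0	0	2	2	0	0	1	0	0	1	1	1	2	0	1	0	0	0	0	0	0	0	N	1	1	1	0	0	1
Physonota alutacea	2	1	0	2	0	0	0	0	1	0	0	0	2	1	0	1	0	0	1	0	0	0	1	1	0	0	0	0	0	0	0	N	1	1	0	1	0	0
Asteriza flavicornis	2	0	1	1	0	0	0	0	1	0	0	0	2	1	0	1	0	0	1	0	0	1	1	1	0	0	0	0	0	0	0	N	1	1	0	1	0	0
Chelymorpha sp.	1	1	0	1	0	0	1	1	1	1	0	0	1	0	0	1	0	0	0	0	0	0	1	1	0	0	0	0	1	0	1	0	1	0	0	1	1	1
Phytodectoidea sp.	1	1	1	1	0	0	1	1	1	1	0	0	1	0	0	1	0	0	0	0	0	0	0	1	0	0	0	0	1	0	1	1	0	0	0	1	1	1
Stolas sp.	1	1	0	1	0	1	1	1	1	2	1	0	0	0	0	0	1	0	0	0	0	0	0	1	0	0	0	0	1	0	0	1	0	2	0	0	?	1
Stoiba angusticollis	1	0	0	2	0	0	1	1	1	1	0	0	2	1	0	1	0	0	1	1	0	1	1	1	0	0	0	0	1	1	1	0	1	0	1	1	1	1
Stoiba bruneri	1	0	0	1	0	0	1	1	1	1	0	0	2	1	0	1	0	0	1	0	0	0	1	1	0	0	0	0	1	1	1	0	1	1	1	1	1	1
Stoiba fascicollis	1	0	1	1	1	0	1	1	1	1	0	0	2	1	0	1	0	0	1	0	0	0	1	1	0	0	0	0	1	0	1	0	1	0	1	1	1	1
Stoiba flavicollis	1	0	0	2	0	0	1	1	1	1	0	0	2	1	0	1	0	0	1	0	0	0	1	1	0	0	0	0	1	$	1	0	1	0	1	1	1	1
Stoiba fuscicornis	1	0	0	1	1	1	1	1	1	1	0	0	2	1	0	1	0	0	1	0	0	0	1	1	0	0	1	0	1	0	1	0	1	0	0	1	1	1
Stoiba indivisa	1	0	0	2	1	0	1	1	1	1	0	0	2	0	0	1	0	0	0	0	0	0	1	1	0	0	1	0	1	0	1	0	1	?	?	1	1	1
Stoiba marginata	1	0	0	2	0	0	1	1	1	1	0	0	2	1	0	1	0	0	1	1	0	1	1	1	0	0	0	0	1	1	1	0	1	0	0	1	1	1
Stoiba nigricans	1	0	0	2	1	0	1	1	1	1	0	0	2	1	0	1	0	0	1	0	0	0	1	1	0	0	0	0	1	1	1	0	1	1	1	1	1	1
Stoiba swartzii	1	0	0	1	1	1	1	1	1	1	0	0	2	1	0	1	0	0	0	0	0	0	1	1	0	0	0	0	1	0	1	0	1	0	0	1	1	1
Elytrogona bacca	1	0	0	2	1	1	1	1	1	2	1	0	0	1	1	0	1	1	2	1	1	2	2	0	1	1	0	2	0	2	1	1	0	1	0	1	1	1
Elytrogona gemmata	1	0	0	2	0	1	1	1	1	2	1	1	0	1	1	0	1	1	2	1	1	2	2	0	1	1	0	1	0	2	1	1	0	1	0	1	1	1
Elytrogona nigrodorsata	1	0	0	2	1	1	1	1	1	2	1	0	0	1	1	0	1	1	2	1	1	2	2	0	1	1	0	2	0	2	1	1	0	1	0	1	1	1
Elytrogona quatuordecimmaculata	1	0	0	2	1	1	1	1	1	2	1	0	0	1	1	0	1	1	2	1	1	2	2	0	1	1	0	2	0	2	1	1	0	1	0	1	1	1
Elytrogona bulla	1	0	0	2	0	1	1	1	1	2	1	1	0	1	1	1	1	?	2	0	0	0	2	0	0	1	0	1	0	2	1	1	1	0	1	1	1	1
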