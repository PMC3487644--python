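0	Head, well exposed=0; mostly concealed=1; entirely concealed=2
1	Antennomeres III–X, mainly pale yellow=0; brown with black or mixed=1
2	Antennomere III, 2 times as long or longer than II=0; less than 2 times=1
3	Antennomere III, shorter than IV=0; as long as IV or slightly longer (1.1 times)=1; distinctly longer (over 1.2 times)=2
4	Antennomere VII, longer than width=0; broader than length or as broad as long=1
5	Mandible, teeth number five=0; 4 or 4 with vestigial teeth=1
6	Mandible, without horizontal thickening=0; with horizontal thickening=1
7	Labial palpomere I shape, sub-quadrate=0; triangular=1
8	Pronotum, anterior edge continuous=0; discontinuous=1
9	Prosternum, antero-lateral edge rounded or slightly angled=0; distinctly angled=1
10	Pronotum, base, angled=0; transverse=1
11	Pronotum, widest at base=0; at middle=1; at front=2
12	Pronotum, basal line, linear=0; sinuate=1; rounded=2
13	Pronotum postero-medial angle extending more than postero-lateral margin=0;; not extended or slightly extended=1
14	Prosternal process, slightly inflated=0; straight sided=1
15	Scutellum, hidden or small=0; well exposed=1
16	Meso-, metanotum, separated=0, fused=1
17	Metasternum, medially broad and flat=0; not flat with deep groove medially=1
18	Elytral disc height/length ratio, less than 0.34=0; between 0.35-0.5=1; over 0.5=2
19	Elytra surface, smooth=0; rough=1
20	Elytral puncture size, small=0; large=1
21	Elytral punctuation, fine=0; rough=1; coarse
22	Base of elytral disc, distinctly broader than discal base of pronotum=0; as broad as or slightly broader=1; narrower=2
23	Elytra, umbone indistinct=0; distinct=1
24	Elytra margin, lateral edge, rounded=0; angled=1
25	Elytra margin expanded toward vento-laterally=0 (81–86); horizontally=1 (87–91)
26	Elytra margin posterior half distinct from disc=0; vague=1
27	Elytral suture, separate=0, partly fused=1, fused=2
28	Elytral longitudinal carina and brace, parallel=0; angled=1
29	Hind wing, fully developed=0; brachypterous=1; vestigial=2
30	Claw basal tooth absent=0; present=1
31	Claw basal part, simple=0; quadrate=1; pointed=2
32	Spermathecal duct, short=0; long=1
33	Spermathecal receptacle, short=0, shorter than ¼ of pump; long, over ¼ of pump length =1
34	Spermathecal duct, loosely coiled=0; tightly coiled=1
35	Male genitalia, deversment=1; without deversment=0
36	Seminal vesicle, much thicker than ejaculatory duct=0; slightly thicker=1
37	Aedeagal spicule, divided into two segments=0; not divided, Y or V-shaped=1
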