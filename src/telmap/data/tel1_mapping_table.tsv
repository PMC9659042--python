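name	family	chrom	coordinate	round	n_recombinants	side
P{PZ}sqz[02102]	P	3R	19165876	1	3	Right
P{lacW}vib[j5A6]	P	3R	19226365	1	6	Right
P{PZ}l(3)05820[05820]	P	3R	19229496	1	3	Right
P{PZ}Dl[05151]	P	3R	19326218	1	2	Right
Mi{MIC}Ino80[MI03112]	Minos	3R	19373898	3	1	Right
Mi{MIC}Ino80[MI02316]	Minos	3R	19388379	3	1	Right
P{XP}Ino80[d10097]	P	3R	19403413	2	6	Left
Mi{ET1}CG31221[MB02141]	Minos	3R	19414147	2	5	Left
P{EPgy2}CG31221[EY10678]	P	3R	19453650	2	4	Left
P{XP}Dys[d03320]	P	3R	19498929	2	3	Left
Mi{ET1}CG6231[MB01639]	Minos	3R	19629652	2	6	Left
P{SUPor-P}CG16718[KG06218]	P	3R	19641774	1	3	Left
P{PZ}Vha13[05113]	P	3R	19644018-19644026	1	3	Left
P{hsneo}l(3)neo50[1]	P	3R	19836871	1	3	Left
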