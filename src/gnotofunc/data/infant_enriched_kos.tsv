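ko	pathway	description	Anaerostipes_sp	C_intestinale	L_johnsonii	L_murinus	E_faecalis	M_sciuri	S_xylosus	K_cowanii	P_distasonis	absent_in
K02793	Fructose and mannose metabolism	manXa; mannose PTS system EIIA component [EC:2.7.1.191]	4	1	1	2	1	1	0	0	0	ASF
K02538	Fructose and mannose metabolism	manR; activator of the mannose operon, transcriptional antiterminator	1	2	1	0	1	2	1	0	0	ASF
K02822	Ascorbate and aldarate metabolism	ulaB, sgaB; ascorbate PTS system EIIB component [EC:2.7.1.194]	3	1	0	0	1	1	1	0	0	ASF
K02552	Ubiquinone and other terpenoid-quinone biosynthesis	menF; menaquinone-specific isochorismate synthase [EC:5.4.4.2]	0	0	0	0	1	1	1	1	1	ASF
K16370	Glycolysis/Gluconeogenesis	pfkB; 6-phosphofructokinase 2 [EC:2.7.1.11]	1	0	1	0	1	0	0	1	0	ASF
K00432	Arachidonic acid metabolism	gpx, btuE, bsaA; glutathione peroxidase [EC:1.11.1.9]	0	2	0	0	0	1	1	2	0	ASF,OMM12
K02768	Fructose and mannose metabolism	fruB; fructose PTS system EIIA component [EC:2.7.1.202]	3	1	0	0	1	1	0	0	0	ASF
K02769	Fructose and mannose metabolism	fruAb; fructose PTS system EIIB component [EC:2.7.1.202]	2	1	0	0	1	1	0	0	0	ASF
K00383	Glutathione metabolism	GSR, gor; glutathione reductase (NADPH) [EC:1.8.1.7]	0	0	1	0	1	1	0	1	0	ASF
K02549	Ubiquinone and other terpenoid-quinone biosynthesis	menC; o-succinylbenzoate synthase [EC:4.2.1.113]	0	0	0	0	1	1	1	1	0	ASF
K08680	Ubiquinone and other terpenoid-quinone biosynthesis	menH; 2-succinyl-6-hydroxy-2,4-cyclohexadiene-1-carboxylate synthase [EC:4.2.99.20]	0	0	0	0	1	1	1	1	0	ASF
K02744	Galactose metabolism	agaF; N-acetylgalactosamine PTS system EIIA component [EC:2.7.1.-]	2	0	1	0	1	0	0	0	0	ASF
K00164	Citrate cycle (TCA cycle)	OGDH, sucA; 2-oxoglutarate dehydrogenase E1 component [EC:1.2.4.2]	0	0	0	0	0	1	1	1	0	ASF
K02753	Glycolysis/Gluconeogenesis	ascF; beta-glucoside (arbutin/salicin/cellobiose) PTS system EIICB component [EC:2.7.1.-]	0	0	0	0	0	1	1	1	0	ASF
K02779	Glycolysis/Gluconeogenesis	ptsG; glucose PTS system EIICB or EIICBA component [EC:2.7.1.199]	0	0	1	0	1	0	0	1	0	ASF
K07406	Galactose metabolism	melA; alpha-galactosidase [EC:3.2.1.22]	0	1	0	0	0	0	1	1	0	ASF
K13954	Glycolysis/Gluconeogenesis	yiaY; alcohol dehydrogenase [EC:1.1.1.1]	1	1	0	1	0	0	0	0	0	ASF
K16869	Lipoic acid metabolism	lipL; octanoyl-[GcvH]:protein N-octanoyltransferase [EC:2.3.1.204]	0	0	0	0	1	1	1	0	0	ASF
K00632	alpha-Linolenic acid metabolism	fadA, fadI; acetyl-CoA acyltransferase [EC:2.3.1.16]	0	0	0	0	0	1	1	2	0	ASF
K07160	Glutathione metabolism	pxpA; 5-oxoprolinase (ATP-hydrolyzing) subunit A [EC:3.5.2.9]	0	0	0	0	0	1	1	1	0	ASF
K00116	Citrate cycle (TCA cycle)	mqo; malate dehydrogenase (quinone) [EC:1.1.5.4]	0	0	0	0	0	2	2	2	0	ASF,OMM12
K00138	Glycolysis/Gluconeogenesis	aldB; aldehyde dehydrogenase [EC:1.2.1.-]	0	0	0	0	0	1	1	1	0	ASF,OMM12
K00241	Citrate cycle (TCA cycle)	sdhC, frdC; succinate dehydrogenase/fumarate reductase, cytochrome b subunit	0	0	0	0	0	1	1	1	0	ASF,OMM12
K13979	Glycolysis/Gluconeogenesis	yahK; alcohol dehydrogenase (NADP+) [EC:1.1.1.2]	0	0	0	0	0	1	1	1	0	ASF,OMM12
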