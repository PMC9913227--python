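# species: Ophichthus evermanni
# genome_length: 17759
gene	strand	start	end	start_codon	stop_codon
tRNA-Phe (F)	H	1	68
12S rRNA	H	69	1027
tRNA-Val (V)	H	1028	1098
16S rRNA	H	1099	2801
tRNA-Leu^UUA^ (L1)	H	2802	2877
ND1	H	2878	3846	ATG	TAA
tRNA-Ile (I)	H	3850	3922
tRNA-Gln (Q)	L	3922	3992
tRNA-Met (M)	H	3992	4060
ND2	H	4061	5117	ATG	T--
tRNA-Trp (W)	H	5118	5186
tRNA-Ala (A)	L	5188	5256
tRNA-Asn (N)	L	5258	5330
O_L	H	5335	5368
tRNA-Cys (C)	L	5375	5439
tRNA-Tyr (Y)	L	5440	5510
CO I	H	5512	7152	GTG	TAG
tRNA-Ser^UCA^ (S1)	L	7169	7239
tRNA-Asp (D)	H	7245	7312
CO II	H	7319	8009	ATG	T--
tRNA-Lys (K)	H	8010	8084
ATP8	H	8086	8253	ATG	TAA
ATP6	H	8244	8926	ATG	TA-
CO III	H	8927	9712	ATG	TAA
tRNA-Gly (G)	H	9712	9783
ND3	H	9784	10132	ATG	T--
tRNA-Arg (R)	H	10133	10202
ND4L	H	10203	10499	ATG	TAA
ND4	H	10493	11873	ATG	T--
tRNA-His (H)	H	11874	11942
tRNA-Ser^AGC^ (S2)	H	11943	12012
tRNA-Leu^CUA^ (L2)	H	12013	12085
ND5	H	12086	13921	ATG	TAA
Cyt b	H	13936	15077	ATG	AA-
tRNA-Thr (T)	H	15095	15166
CR1	H	15167	16132
ND6	L	16133	16651	CTA	CAT
tRNA-Glu (E)	L	16652	16720
tRNA-Pro (P)	L	16724	16794
CR2	H	16795	17759
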