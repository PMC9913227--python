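# species: Ophichthus erabo
# genome_length: 17856
gene	strand	start	end	start_codon	stop_codon
tRNA-Phe (F)	H	1	69
12S rRNA	H	70	1036
tRNA-Val (V)	H	1037	1107
16S rRNA	H	1108	2812
tRNA-Leu^UUA^ (L1)	H	2813	2888
ND1	H	2889	3857	ATG	TAG
tRNA-Ile (I)	H	3861	3933
tRNA-Gln (Q)	L	3933	4003
tRNA-Met (M)	H	4003	4071
ND2	H	4072	5128	ATG	T--
tRNA-Trp (W)	H	5129	5200
tRNA-Ala (A)	L	5202	5270
tRNA-Asn (N)	L	5272	5344
O_L	H	5351	5376
tRNA-Cys (C)	L	5394	5459
tRNA-Tyr (Y)	L	5460	5530
CO I	H	5532	7172	GTG	TAA
tRNA-Ser^UCA^ (S1)	L	7191	7261
tRNA-Asp (D)	H	7267	7334
CO II	H	7341	8031	ATG	T--
tRNA-Lys (K)	H	8032	8106
ATP8	H	8108	8275	ATG	TAA
ATP6	H	8266	8949	ATG	TAA
CO III	H	8949	9734	ATG	TAA
tRNA-Gly (G)	H	9734	9805
ND3	H	9806	10154	GTG	T--
tRNA-Arg (R)	H	10155	10224
ND4L	H	10225	10521	ATG	TAA
ND4	H	10515	11895	ATG	T--
tRNA-His (H)	H	11896	11964
tRNA-Ser^AGC^ (S2)	H	11965	12034
tRNA-Leu^CUA^ (L2)	H	12035	12107
ND5	H	12108	13943	ATG	TAA
Cyt b	H	13959	15098	ATG	TAA
tRNA-Thr (T)	H	15116	15187
CR1	H	15188	16224
ND6	L	16225	16743	CTA	CAT
tRNA-Glu (E)	L	16744	16812
tRNA-Pro (P)	L	16820	16890
CR2	H	16891	17856
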