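patient_id	etiology	subtype	gene	variant	zygosity	printed_class	sources
HTP070	IPAH		BMPR2	NM_001204.6:c.77-5_77-2delTTTA	Het	P	T1
HTP070	IPAH		NOTCH3	NM_000435.2:c.181C>T:p.(Arg61Trp)	Het	VUS	T1
HTP081	IPAH		NOTCH3	NM_000435.2:c.1964A>G:p.(Asn655Ser)	Het	VUS	T1
HTP466	IPAH		ABCC8	NM_000352.4:c.3976G>A:p.(Glu1326Lys)	Het	LP	T1;T2
HTP466	IPAH		NOTCH3	NM_000435.2:c.6532C>T:p.(Pro2178Ser)	Het	VUS	T1
HTP474	CHD		ABCC8	NM_000352.4(ABCC8):c.3394G>A:p.(Asp1132Asn)	Het	VUS	T1;T2;T3
HTP474	CHD		SARS2	NM_017827.3:c.136G>A:p.(Glu46Lys)	Het	VUS	T1;T3
HTP611	CHD		TBX4	NM_018488.3:c.1018C>T:p.(Arg340*)	Het	P	T1;T3
HTP611	CHD		SMAD1	NM_005900.2:c.738G>C:p.(Met246Ile)	Het	VUS	T1;T3
HTP114	IPAH		ABCC8	NM_000352.4:c.1643C>T:p.(Thr548Met)	Het		T2
HTP88	IPAH		ABCC8	NM_000352:exon26:c.3288_3289del:p.(His1097Profs*16)	Het		T2
HTP151	IPAH		ABCC8	NM_000352.4:c.3238G>A:p.(Val1080Ile)	Het		T2
HTP159	IPAH		ABCC8	NM_000352.4:c.2422C>A:p.(Gln808Lys)	Het		T2
HTP162	IPAH		ABCC8	NM_000352.4:c.1429G>A:p.(Val477Met)	Het		T2
HTP37	IPAH		ABCC8	NM_000352.3:c.579+5G>A	Het		T2
HTP78	CTD	CREST	ABCC8	NM_000352.3:c.2694+1G>A	Het	VUS	T2;T3
HTP501	CHD		CPS1	NM_001122633.2(CPS1):c.3047C>T:p.(Thr1016Met)	Hom	VUS	T3
HTP536	CHD		BMPR2	NM_001204.6:c.2674delG:p.(Glu892Asnfs*4)	Het	P	T3
HTP541	CHD		BMPR2	NM_001204.6:c.2674delG:p.(Glu892Asnfs*4)	Het	P	T3
HTP558	CHD		SMAD5	NM_001001420.2:c.763A>G:p.(Ile255Val)	Het	VUS	T3
HTP262	CHD		NOTCH3	NM_000435.3:c.6097C>G:p.(Pro2033Ala)	Het	VUS	T3
HTP472	CHD		CPS1	NM_001122633.2:c.1036G>A:p.(Ala346Thr)	Het	VUS	T3
HTP551	CTD		GDF2	NM_016204:c.642G>A:p.(Trp214*)	Het	VUS	T3
HTP355	CTD		CPS1	NM_001875.4:c.4252C>T:p.(Pro1418Ser)	Het	VUS	T3
HTP452	CTD		NOTCH3	NM_000435:c.5203G>A:p.(Glu1735Lys)	Het	VUS	T3
HTP564	CTD		TBX4	NM_018488.2:c.1112dupC:p.(Pro372Serfs*14)	Het	P	T3
PVOD_HOM1	PVOD		EIF2AK4	NM_001013703.3:c.3344C>T:p.(Pro1115Leu)	Hom	P	S3
PVOD_SIB1	PVOD		EIF2AK4	NM_001013703.3:c.3766C>T:p.(Arg1256*)	Het	P	S3
PVOD_SIB1	PVOD		EIF2AK4	NM_001013703.3:c.4392dup:p.(Lys1465*)	Het	P	S3
PVOD_SIB2	PVOD		EIF2AK4	NM_001013703.3:c.3766C>T:p.(Arg1256*)	Het	P	S3
PVOD_SIB2	PVOD		EIF2AK4	NM_001013703.3:c.4392dup:p.(Lys1465*)	Het	P	S3
IPAH_CBLN2	IPAH		CBLN2	NM_182511.3:c.263C>T:p.(Ser88Phe)	Het	VUS	S3
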