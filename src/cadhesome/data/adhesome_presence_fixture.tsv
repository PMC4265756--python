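family_id	Hs	Mm	Gg	Xt	Dr	Ci	Bf	Sp	Dm	Ce	Hv	Nv	Ta	Aq	Oc	Mb	Sr	Co	Sa	Am	Mv	Spu	Sc	Spo	Dd	Tt
VEZT	1	0	1	0	1	1	0	1	1	1	1	0	0	1	1	1	1	1	1	1	0	1	1	1	0	1
MYO7A	1	0	1	0	1	1	1	1	0	1	1	0	1	1	1	0	1	1	1	1	1	1	1	1	0	1
CTNNA_VCL	1	0	1	1	1	1	1	1	1	1	1	1	0	1	0	1	1	0	0	0	1	1	0	0	1	1
CTNNB_AARDVARK	1	1	1	1	1	1	1	1	0	1	1	0	1	1	1	1	0	1	1	1	1	1	1	1	0	1
PRE_A01	1	0	1	1	1	0	1	0	1	1	1	0	1	0	1	1	0	0	0	0	0	0	1	1	1	0
PRE_A02	1	1	1	1	1	0	0	1	0	0	1	0	1	0	0	1	1	1	1	1	1	1	1	0	0	1
PRE_A03	1	1	1	1	1	0	1	1	0	0	0	1	1	1	1	1	1	1	1	0	1	0	1	0	1	1
PRE_A04	1	1	0	0	1	1	0	0	0	1	1	0	1	0	0	0	1	1	0	0	0	1	1	1	1	0
PRE_A05	1	1	1	1	1	0	1	1	1	1	1	0	1	0	1	1	0	0	1	1	0	1	0	1	1	1
PRE_A06	1	1	1	1	1	1	1	1	0	1	0	1	1	1	1	0	1	1	1	1	0	1	1	1	1	1
PRE_A07	1	1	1	0	0	1	1	0	0	1	1	1	1	0	0	1	1	0	1	1	1	1	1	1	0	1
PRE_A08	1	1	1	1	1	1	0	1	0	1	0	0	1	0	1	0	1	0	1	1	1	1	1	0	1	1
PRE_A09	1	1	1	0	0	0	0	0	0	1	0	0	0	1	1	1	1	0	0	1	0	1	1	0	1	1
PRE_A10	1	0	0	0	1	1	1	0	0	1	1	1	1	0	0	1	1	0	1	0	0	1	1	1	1	1
PRE_A11	1	0	1	0	1	1	1	0	1	1	1	1	1	0	1	1	1	1	0	1	1	1	1	0	1	1
PRE_A12	1	1	1	0	1	1	0	1	1	1	1	0	0	1	1	0	0	1	1	0	1	0	1	0	1	1
PRE_A13	1	1	1	0	0	1	0	1	1	1	1	0	0	0	1	0	1	1	1	0	1	0	1	1	0	1
PRE_A14	1	0	0	1	0	1	1	1	1	1	1	0	0	1	0	1	1	1	1	1	1	0	1	1	1	1
PRE_A15	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	1	1	0	1	1	1	1	1
PRE_A16	1	1	1	1	0	1	1	1	0	1	1	0	1	0	0	1	1	0	1	0	1	1	0	0	1	1
PRE_A17	1	0	0	1	1	1	0	1	1	1	0	1	0	1	1	0	0	1	0	1	1	1	1	0	1	0
PRE_A18	1	1	0	0	1	1	1	1	1	0	1	1	1	1	1	1	1	0	1	0	1	0	1	0	0	1
PRE_A19	1	0	1	1	1	1	1	1	1	0	1	1	1	1	1	1	0	1	1	1	1	1	1	0	1	1
PRE_A20	1	0	0	1	0	1	1	0	0	1	0	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1
PRE_A21	1	1	1	0	0	1	1	0	1	1	1	1	0	1	1	0	1	1	1	0	1	1	1	1	1	1
PRE_A22	1	1	1	1	1	1	1	1	1	0	0	1	1	1	1	1	1	1	1	1	1	1	1	0	1	1
PRE_A23	1	1	1	0	1	0	1	1	1	1	1	1	1	1	0	1	1	1	1	0	1	1	0	0	0	1
PRE_A24	1	0	1	1	1	0	0	0	1	0	1	0	0	0	1	0	0	1	1	0	1	0	0	0	1	1
PRE_A25	1	0	1	1	1	0	1	1	1	0	1	1	0	1	1	0	1	0	0	1	1	1	0	0	1	1
PRE_A26	1	1	1	0	0	1	0	0	1	1	1	1	0	1	1	1	1	1	1	1	1	1	1	1	0	1
PRE_A27	1	1	0	1	1	0	1	1	1	0	1	0	1	1	1	1	1	0	0	1	0	0	1	1	1	0
PRE_A28	1	0	0	1	1	1	0	0	1	1	1	0	0	1	0	1	1	0	1	1	1	0	1	1	1	1
PRE_A29	1	1	1	0	1	0	0	1	0	1	1	1	1	0	0	1	1	1	1	0	1	1	1	1	1	1
PRE_A30	1	1	1	1	0	1	0	1	0	1	0	1	1	1	1	1	1	1	0	0	1	1	1	1	1	1
PRE_A31	1	1	1	1	1	0	0	1	1	1	0	1	1	1	0	0	1	1	1	1	1	0	1	0	1	1
PRE_A32	1	1	1	1	1	0	1	1	1	0	1	1	1	1	0	1	1	0	1	0	1	1	1	1	1	0
PRE_A33	1	1	1	1	0	1	1	0	1	1	1	1	0	1	0	1	1	0	1	1	1	1	1	1	1	0
PRE_A34	1	0	1	1	1	1	1	1	0	1	1	0	0	0	0	1	1	1	1	0	1	0	1	0	0	1
PRE_A35	1	0	1	0	1	1	1	1	1	1	1	0	1	1	1	1	1	1	0	1	1	0	1	1	0	1
PRE_A36	1	1	1	1	1	1	0	1	1	0	1	1	1	0	1	0	1	1	1	0	1	0	0	0	1	1
PRE_A37	1	1	1	1	1	1	1	1	0	1	1	1	1	0	1	0	1	1	1	1	1	0	1	1	1	1
PRE_A38	1	1	1	0	1	1	1	0	1	0	0	1	1	0	1	1	0	0	0	0	1	0	1	0	1	0
PRE_A39	1	0	0	0	0	1	1	1	1	1	1	1	1	1	1	0	1	1	1	0	0	1	1	1	0	1
PRE_A40	1	1	1	1	0	1	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	1	1	1	0	1
PRE_A41	1	0	1	0	1	1	1	1	1	1	1	1	0	1	1	0	1	0	0	1	0	0	1	1	1	1
PRE_F01	1	1	1	1	0	1	1	1	1	1	1	1	1	0	0	1	1	0	0	0	1	0	1	0	0	0
PRE_F02	1	1	0	1	0	1	1	1	1	0	0	0	1	1	0	1	0	1	1	0	1	1	1	0	0	0
PRE_F03	1	1	1	1	1	1	1	1	1	0	1	0	0	0	1	0	1	1	0	1	0	1	0	0	0	0
PRE_F04	1	0	1	0	1	1	0	0	1	1	0	1	1	0	0	1	1	1	0	1	0	0	0	1	0	0
PRE_F05	1	1	1	1	1	1	1	1	1	0	1	1	0	1	1	1	0	1	1	1	1	0	0	1	0	0
PRE_F06	1	0	1	1	1	1	1	1	1	0	1	0	1	1	0	1	1	1	1	0	1	0	1	0	0	0
PRE_F07	1	1	1	1	0	1	0	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	0	0
PRE_F08	1	0	1	0	1	0	1	1	1	0	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0	0
TIAM1	1	1	1	1	1	0	1	0	1	1	1	1	1	1	1	1	0	0	1	0	0	0	0	0	0	0
SIPA1L3	1	0	1	1	1	1	1	0	1	1	1	0	1	1	1	0	1	0	1	0	0	0	0	0	0	0
RAPGEF2	1	1	0	1	1	1	1	1	1	1	1	0	1	0	1	0	1	1	1	0	0	0	0	0	0	0
HOL_I01	1	0	1	1	1	1	1	1	1	1	1	1	0	1	0	0	1	1	1	0	0	0	0	0	0	0
HOL_I02	1	0	1	1	1	0	1	0	1	1	1	1	1	1	1	0	1	0	1	0	0	0	0	0	0	0
HOL_I03	1	1	1	0	1	1	1	1	1	0	1	1	0	1	1	1	0	1	1	0	0	0	0	0	0	0
HOL_I04	1	0	1	1	0	1	0	1	1	1	1	1	0	1	1	0	1	1	1	0	0	0	0	0	0	0
HOL_I05	1	1	1	1	0	0	1	1	1	1	1	0	1	1	1	0	1	1	1	0	0	0	0	0	0	0
HOL_I06	1	0	1	1	0	1	1	1	1	1	0	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0
SDCBP	1	1	1	1	1	1	0	1	0	1	1	1	0	1	1	1	1	1	0	0	0	0	0	0	0	0
LIN7A	1	1	1	1	1	1	1	1	1	1	1	0	1	0	1	1	1	1	0	0	0	0	0	0	0	0
MAGI	1	1	0	1	1	1	1	1	1	1	0	0	0	1	1	1	0	1	0	0	0	0	0	0	0	0
HOL_F01	1	1	1	0	0	1	1	1	1	0	1	1	1	0	0	1	0	1	0	0	0	0	0	0	0	0
HOL_F02	1	0	1	1	0	1	1	0	1	0	0	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0
HOL_F03	1	1	0	0	1	1	0	1	0	0	1	1	1	1	1	0	1	1	0	0	0	0	0	0	0	0
HOL_F04	1	1	1	1	1	1	1	1	0	0	1	1	0	1	0	0	0	1	0	0	0	0	0	0	0	0
HOL_F05	1	1	1	1	0	1	0	1	0	1	1	1	1	1	0	1	1	1	0	0	0	0	0	0	0	0
HOL_F06	1	1	1	1	0	1	1	0	0	1	0	0	1	1	1	0	1	1	0	0	0	0	0	0	0	0
DLG1	1	1	1	1	1	0	1	1	0	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0
DLG5	1	1	1	0	1	1	1	1	0	1	1	1	1	1	0	1	1	0	0	0	0	0	0	0	0	0
HOL_C01	1	0	1	1	1	1	1	1	1	1	1	0	1	1	0	1	1	0	0	0	0	0	0	0	0	0
HOL_C02	1	1	1	1	1	0	1	1	0	1	0	1	1	1	0	1	1	0	0	0	0	0	0	0	0	0
HOL_C03	1	1	0	1	1	1	0	1	1	1	1	1	1	1	1	0	1	0	0	0	0	0	0	0	0	0
HOL_C04	1	1	0	1	1	1	0	1	0	0	1	1	1	1	0	1	1	0	0	0	0	0	0	0	0	0
HOL_C05	1	1	0	1	0	1	1	1	1	0	1	1	0	1	1	1	1	0	0	0	0	0	0	0	0	0
HOL_C06	1	0	0	1	1	0	1	0	0	0	1	1	1	0	1	1	1	0	0	0	0	0	0	0	0	0
HOL_C07	1	1	1	0	1	0	1	1	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0
CDH_CLASSICAL	1	1	1	1	1	1	1	1	1	0	0	1	1	0	1	0	0	0	0	0	0	0	0	0	0	0
MLLT4	1	0	1	1	1	0	0	0	1	1	1	1	0	1	1	0	0	0	0	0	0	0	0	0	0	0
SORBS	1	1	0	0	1	1	1	1	1	1	1	0	1	0	1	0	0	0	0	0	0	0	0	0	0	0
PDZD2	1	0	1	1	0	1	1	1	1	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0
EPB41	1	0	0	1	1	1	0	1	1	1	0	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0
PARD3	1	0	0	0	1	1	1	1	0	0	1	0	1	0	1	0	0	0	0	0	0	0	0	0	0	0
SCRIB	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0
MET_P01	1	1	0	1	1	1	1	0	0	1	1	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
MET_P02	1	1	0	1	1	0	1	1	1	1	1	0	1	1	1	0	0	0	0	0	0	0	0	0	0	0
MET_P03	1	1	0	0	1	0	1	1	0	1	0	0	1	1	1	0	0	0	0	0	0	0	0	0	0	0
MET_P04	1	1	1	0	0	0	0	1	0	0	0	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0
MET_P05	1	1	1	1	1	0	1	1	1	1	1	1	1	0	1	0	0	0	0	0	0	0	0	0	0	0
MET_P06	1	1	1	0	1	0	1	1	1	1	1	1	1	0	1	0	0	0	0	0	0	0	0	0	0	0
MET_P07	1	0	1	0	1	1	0	1	1	0	1	0	1	1	1	0	0	0	0	0	0	0	0	0	0	0
MET_P08	1	1	1	1	1	1	1	1	0	1	1	1	0	1	0	0	0	0	0	0	0	0	0	0	0	0
MET_P09	1	1	1	0	1	1	0	1	1	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0
MET_P10	1	1	1	0	0	0	1	1	0	1	1	0	1	0	1	0	0	0	0	0	0	0	0	0	0	0
TRIOBP	1	0	1	1	1	1	1	0	1	0	0	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
MET_T01	1	1	1	1	1	0	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
MET_T02	1	0	1	1	1	0	0	1	1	1	1	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
MET_T03	1	1	1	1	1	1	1	1	1	0	0	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
SHROOM3	1	0	1	0	1	1	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
MET_C01	1	0	1	0	1	0	1	0	1	0	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
MET_C02	1	0	0	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
MET_C03	1	1	1	0	0	0	1	0	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
PALLD	1	0	1	0	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
MET_B01	1	0	0	1	0	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
MET_B02	1	1	1	1	1	0	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CGNL1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
MET_CH01	1	1	1	1	0	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
MET_V01	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
MET_V02	1	0	0	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
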