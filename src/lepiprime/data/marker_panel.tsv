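gene	length_bp	n_success	variable_pct	parsinf_pct	conserved_pct	freq_A	freq_T	freq_C	freq_G	gene_db_id	panel
AFG3a	336	22	39.3	37.5	60.7	28.0	27.7	20.2	24.1	BGIBMGA010088	new
AFG3b	300	11	47.3	39.7	52.7	34.9	20.9	20.7	23.6	BGIBMGA010088	new
ANK13C	330	20	49.1	38.8	50.9	33.0	28.5	16.4	22.2	BGIBMGA007536	new
ArgK	388	24	44.6	33.5	55.4	22.9	19.0	32.1	26.1	BGIBMGA005812	new
Ca-ATPase	444	23	37.2	30.2	62.8	24.9	21.0	30.1	24.0	BGIBMGA000408	new
Ca2	410	18	44.9	38.5	55.1	33.2	23.6	18.5	24.7	BGIBMGA006603	new
chitinase	405	18	47.2	40.5	52.8	25.7	27.4	23.8	23.2	BGIBMGA008709	new
Cullin5	327	22	48.3	41.0	51.7	33.4	28.7	17.5	20.5	BGIBMGA011511	new
CycY	375	18	39.7	35.5	60.3	29.9	31.4	17.2	21.6	BGIBMGA005969	new
DDX23	303	24	46.9	43.2	53.1	40.4	22.6	13.8	23.2	BGIBMGA003429	new
Exp1	729	15	43.6	35.8	56.4	31.4	28.2	19.5	21.0	BGIBMGA010657	new
FCF1	173	17	49.7	42.8	50.3	32.4	27.7	16.2	23.7	BGIBMGA010318	new
GLYP	384	14	52.3	44.0	47.7	27.2	24.8	25.1	22.9	BGIBMGA010361	new
KRR1	283	16	47.0	39.2	53.0	35.4	26.4	18.0	20.2	BGIBMGA005381	new
LeuZip	372	9	49.5	35.8	50.5	36.4	24.8	18.0	20.9	BGIBMGA003300	new
MK6	255	20	52.2	45.1	47.8	32.8	28.1	18.6	20.6	BGIBMGA005641	new
MMP41	285	21	56.5	48.1	43.5	31.1	30.6	19.7	18.6	BGIBMGA007574	new
MPP2	330	21	44.9	40.3	55.2	29.0	29.4	22.6	19.1	BGIBMGA008312	new
NC	573	15	48.9	39.6	51.1	32.2	29.1	17.0	21.7	BGIBMGA005035	new
Nex9	420	21	60.5	47.4	39.5	33.1	24.8	19.0	23.2	BGIBMGA001032	new
PolII	360	22	43.9	39.4	56.1	30.1	25.3	19.7	24.8	BGIBMGA004994	new
ProSup	432	22	58.8	47.5	41.2	25.6	27.8	21.0	25.6	BGIBMGA004645	new
PSb	366	23	54.4	45.9	45.6	24.8	23.9	26.7	24.7	BGIBMGA000201	new
SARAH	381	16	56.4	44.9	43.6	29.2	27.8	23.3	19.7	BGIBMGA011095	new
Ssu72	249	23	55.0	48.2	45.0	36.0	28.1	16.0	19.9	BGIBMGA000925	new
TIF3Cb	324	13	50.6	40.1	49.4	24.7	22.1	28.9	24.3	BGIBMGA012851	new
TIF6	336	18	50.0	42.6	50.0	24.4	21.4	25.5	28.8	BGIBMGA009830	new
UDPG6DH	405	21	49.1	41.0	50.9	30.1	27.4	20.9	21.6	BGIBMGA012188	new
VPS4	432	15	40.7	35.4	59.3	28.9	28.9	20.1	22.1	BGIBMGA005930	new
WD40	339	21	42.5	38.6	57.5	30.1	31.4	19.3	19.2	BGIBMGA006243	new
CAD	826	24	52.4	42.7	47.6	35.9	28.3	14.6	21.2		reference
COI	1476	23	44.4	33.0	55.6	31.1	40.0	14.9	14.0		reference
EF1a	1047	21	34.9	27.2	65.1	25.4	23.0	27.6	24.0		reference
GAPDH	691	12	38.9	30.8	61.1	23.6	25.8	27.3	23.3		reference
IDH	722	23	48.2	41.1	51.8	31.2	27.1	19.8	21.9		reference
MDH	407	23	47.9	41.3	52.1	27.4	25.8	22.7	24.1		reference
RpS5	603	20	38.5	34.3	61.5	25.4	24.9	24.4	25.3		reference
wingless	400	20	58.5	48.5	41.5	21.7	18.3	28.9	31.0		reference
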