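name	sequence
AFG3a_F	TAATACGACTCACTATAGGGTGTGAAGAAGCTAAGatwgaratyatggartt
AFG3a_R	ATTAACCCTCACTAAAGGGTGTTGTTGTATTAAAAccrtccatytchac
AFG3b_F	TAATACGACTCACTATAGGGTGCTCAAGACGACCtdaaraaratmac
AFG3b_R	ATTAACCCTCACTAAAGGGCCTGTACCTTCCACGaaytcytcrtamgt
ANK13C_F	TAATACGACTCACTATAGGGCAAATACAAAATTTTTATATGGAAytdaartgggaytt
ANK13C_R	ATTAACCCTCACTAAAGGGGCAACTGTTTCTTTTCTAtcytcwcgraadatcca
ArgK_F	TAATACGACTCACTATAGGGyGAyCCsATCATyGAGGACTACCA
ArgK_R	ATTAACCCTCACTAAAGGGAGrTGGTCCTCCTCrTTGCACCAvAC
Ca2_F	TAATACGACTCACTATAGGGAAACAGTGGACtgyttgaaraarttcaayg
Ca2_R	ATTAACCCTCACTAAAGGGGGTGTGTTGTCGATGaaraayttrtgraa
Ca-ATPase_F	TAATACGACTCACTATAGGGGAAtacgarccbgaaatgggwaargt
Ca-ATPase_R	ATTAACCCTCACTAAAGGGcdccrtgrgcggggtcgttraagtg
chitinase_F	TAATACGACTCACTATAGGGGGTGGGTGCTtayttygtngaatgggg
chitinase_R	ATTAACCCTCACTAAAGGGTGTCCACAccrtcraaraayttcca
Cullin5_F	TAATACGACTCACTATAGGGTGTTAGTTAAAGATGCTTTTATGgaygaycchmg
Cullin5_R	ATTAACCCTCACTAAAGGGTCTTAACCATTCAaccatrtcytcttcyttytc
CycY_F	TAATACGACTCACTATAGGGgattatgayaartataatccwgaacayaaaca
CycY_R	ATTAACCCTCACTAAAGGGcattgcytcyaatttytgtgcyctttcytt
DDX23_F	TAATACGACTCACTATAGGGACAAAAGATAAAGAACGTgargargargchat
DDX23_R	ATTAACCCTCACTAAAGGGTGATCTTTTTCAgaccartghckrtcatccca
Exp1_F	TAATACGACTCACTATAGGGgthaataaaytdtttgaattyatgcatga
Exp1_R	ATTAACCCTCACTAAAGGGggrtaytcttcaaartctttrttdatcat
FCF1_F	TAATACGACTCACTATAGGGACTGGACATCGtdcarartatgatggayt
FCF1_R	ATTAACCCTCACTAAAGGGTTGTAGCCACGATGtarcayttrtgytg
GLYP_F	TAATACGACTCACTATAGGGACTGCGACAAGAAtayttyatgtgygcbgc
GLYP_R	ATTAACCCTCACTAAAGGGTTCACTCGTTTTTCACCTtcytcytcdat
KRR1_F	TAATACGACTCACTATAGGGaatgcktggrctatgaaratwcc
KRR1_R	ATTAACCCTCACTAAAGGGtdataatrtcrcatccwatttcrtc
LeuZip_F	TAATACGACTCACTATAGGGTGCCTGTCACAAaaygaytggaaryt
LeuZip_R	ATTAACCCTCACTAAAGGGTTTGACCAGGGTTTttdgcrtarttraa
MK6_F	TAATACGACTCACTATAGGGTTAGAGAAGGTGATgtntggathtgyatgga
MK6_R	ATTAACCCTCACTAAAGGGTTCTTTCTGGTGCCATGtanggyttrca
MMP41_F	TAATACGACTCACTATAGGGGAAAACTGGGGTGCTAAagtdtayttyaaya
MMP41_R	ATTAACCCTCACTAAAGGGTCACTTTGtttttrttytchccaaawgtcat
MPP2_F	TAATACGACTCACTATAGGGCACTTCCGAATCccdtggttycartaycc
MPP2_R	ATTAACCCTCACTAAAGGGCCACAGCAGCTGTGtaytcyttdccraa
NC_F	TAATACGACTCACTATAGGGgatgaagaaaaycchaaraarttytt
NC_R	ATTAACCCTCACTAAAGGGacwatdgaccartggaarttcatdgc
Nex9_F	TAATACGACTCACTATAGGGTGCAACTGCAAgartttgtngaytggatg
Nex9_R	ATTAACCCTCACTAAAGGGCCCAGTCGTATTTAggytgbtcntcatacat
PolII_F	TAATACGACTCACTATAGGGCTGAAACACCTACAatggcbathgaytgggt
PolII_R	ATTAACCCTCACTAAAGGGGCTGTAGGGTTCCATttdgcrtgytcytt
ProSup_F	TAATACGACTCACTATAGGGGACAACAATCGACtggcayccnaayaa
ProSup_R	ATTAACCCTCACTAAAGGGCTGTCCAGTgactggaayttyttcatdgc
PSb_F	TAATACGACTCACTATAGGGGCTGGGAGCTACTggvtgytggtgygaya
PSb_R	ATTAACCCTCACTAAAGGGAGATGCAGTCTCCAGTGTAGatrtcdckytc
SARAH_F	TAATACGACTCACTATAGGGGAAGATGGTATGCCTAATAtwcaycchaayat
SARAH_R	ATTAACCCTCACTAAAGGGGTTCACCTTCTTCACGAggytcccadccna
Ssu72_F	TAATACGACTCACTATAGGGCAGCTGACAGACCTaaytgttaygarttygg
Ssu72_R	ATTAACCCTCACTAAAGGGCCGATTGTAGCTTCTtcrtgrttrtcytg
TIF3Cb_F	TAATACGACTCACTATAGGGGAAAAATCGACCACCTGtaytayaarttyga
TIF3Cb_R	ATTAACCCTCACTAAAGGGGCCAGCAGTTCTTTAggyttnccvgtcatca
TIF6_F	TAATACGACTCACTATAGGGCTGTGCGAGTGcarttygaraayaataa
TIF6_R	ATTAACCCTCACTAAAGGGTGTGTCAGCCAGGatytcytchgtrtc
UDPG6DH_F	TAATACGACTCACTATAGGGCAGGAACTGTGTtgggtvtaygarcaytg
UDPG6DH_R	ATTAACCCTCACTAAAGGGTCTTGTGTCGCCTgtrttyttyttraa
WD40_F	TAATACGACTCACTATAGGGGATCCACTTCACAcaygcyaaraayac
WD40_R	ATTAACCCTCACTAAAGGGCCTgtccartcacaytcyttytcttg
VPS4_F	TAATACGACTCACTATAGGGTGATTCTGATGATCCAGAAaaraaraaryt
VPS4_R	ATTAACCCTCACTAAAGGGCATCCATATCAttvccdacaccttgcatytg
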