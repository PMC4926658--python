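voucher	family	genus	species	n_genes_sequenced
MM00058	Micropterigidae	Micropterix	aureatella	11
MM00867	Nepticulidae	Ectoedemia	occultella	18
MM00943	Tischeriidae	Tischeria	ekebladella	18
MM02175	Psychidae	Taleporia	tubulosa	22
MM00030	Gracillariidae	Gracillaria	syringella	26
MM00306	Yponomeutidae	Yponomeuta	evonymellus	27
MM00510	Tortricidae	Tortrix	viridana	22
MM00014	Schreckensteiniidae	Schreckensteinia	festaliella	26
MM02524	Epermeniidae	Epermenia	illigerella	24
MM03096	Pterophoridae	Stenoptilia	veronicae	22
MM00913	Alucitidae	Alucita	hexadactyla	19
MM03941	Choreutidae	Choreutis	pariana	21
MM00021	Urodidae	Wockia	asperipunctella	17
MM00116	Cossidae	Cossus	cossus	28
MM00125	Sesiidae	Synanthedon	scoliaeformis	29
MM00312	Zygaenidae	Adscita	statices	26
MM00034	Hesperiidae	Pyrgus	malvae	24
MM00042	Elachistidae	Ethmia	pusiella	25
MM00051	Pyralidae	Pyralis	farinalis	24
MM00027	Drepanidae	Thyatira	batis	28
MM00032	Geometridae	Cyclophora	punctaria	26
MM00394	Endromidae	Endromis	versicolora	29
MM01170	Noctuidae	Apamea	crenata	27
MM02696	Lasiocampidae	Poecilocampa	populi	24
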