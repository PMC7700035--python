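Compound,VEGFA (1VPF),TNF (2AZ5),PIK3CG (2CHZ),PTGS2 (5KIR),MAPK1 (5NHV)
Protopine,−7.8,−9.2,−9.4,−5.4,−9.5
Cavidine,−7.4,−8.4,−8.6,−5.1,−9.3
Rutaecarpine,−7.8,−9.8,−9.2,−8.9,−9.1
8-(3-Methylbut-2-enyl)-2-phenylchromen-4-one,−7.5,−8.7,−9.6,−10.7,−9
Luteolin,−7.2,−7.8,−8.8,−9.7,−8.6
Quercetin,−7.2,−7.2,−7.7,−9.7,−8.6
Isorhamnetin,−7.2,−7.3,−7.8,−9.7,−8.5
Berberine,−7.2,−8.6,−8.5,−6,−8.5
Liquiritigenin,−7.3,−7.6,−8.8,−9.3,−8.4
Kaempferol,−6.9,−6.9,−7.5,−9.8,−8.3
Stigmasterol,−6.9,−8.3,−8.3,−7.9,−8.2
Phellopterin,−6.5,−7.4,−8,−8.3,−8.1
Palmatine,−6.2,−8,−7.5,−5.2,−7.8
Isocorypalmine,−7,−7.8,−7.7,−4.9,−7.7
Anhydroicaritin,−7.7,−8,−8.6,6.6,−7.5
2-7-Dihydrohomoerysotrine,−6,−7.4,−7.1,−2.8,−6.3
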