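name	binding_assay	transport_assay	prior_validation	reference
Citric acid	X
Alpha ketoglutaric acid	X
Succinic acid	X
D-+-Malic acid	X
Elaidic acid	X
Cis-aconitic acid	X
Arabinose	X
Rutin	X
Biochanin A	X		X	B44
Chrysin	X		X	B44
Ginkgolide B	X		X	B44
P-hydroxycinnamic acid	X
Serotonin	X
N-acetylglycine	X
Homovanillic acid	X
Saccharin	X
Ascorbic acid	X
Folic acid	X
Thiamine hydrochloride	X
Ergocalciferol	X
Niacin	X	X
Skatole		X
3-Indoleacrylic acid		X
Fisetin			X	B45
Galangin			X	B45
Luteolin			X	B45
Morin			X	B45
Myricetin			X	B44
Silymarin			X	B44
Diosmin			X	B44
Genistein			X	B44
Quercetin			X	B44
Phloridzin			X	B44
Lithospermic acid			X	B46
Rosmarinic acid			X	B47
Salvianolic acid A			X	B47
Rhein			X	B47
Wogonin			X	B48
Baicalein			X	B48
Aristolochic acid (AA-I)			X	B49
Aristolochic acid (AA-II)			X	B49
Gallic acid			X	B50
Ferulic acid			X	B50
Protocatechuic acid			X	B50
Sinapinic acid			X	B50
Vanillic acid			X	B50
1,3-dicaffeoylquinic acid			X	B50
18β-Glycyrrhetinic acid			X	B50
Silybin			X	B51
Emodin			X	B52
Aloe emodin			X	B52
Apigenin			X	B53
Chrysophanol			X	B54
Obtusifolin			X	B54
Quercetin-3-O-glucuronide			X	B55
Ellagic acid			X	B56
Flavone			X	B57
5,6,2′,6′-tetramethoxyflavone			X	B57
Wedelolactone			X	B58
Calycosin			X	B58
Oroxylin A			X	B58
Viscidulin III			X	B58
Scullcapflavone II			X	B58
Ginkgolide A			X	B59
Bilobalide			X	B59
Neochamaejasmine A			X	B60
(−)-epigallocatechin-3-gallate (EGCG)			X	B23
Cinnamic acid		X	X	B26
Indoxyl sulfate potassium salt			X	B26
4-Hydroxyphenylpyruvic acid			X	B26
4-hydroxyphenylacetic acid			X	B26
3-indoacetic acid			X	B26
2-oxindole			X	B26
Tyramine			X	B26
Indole-3-carboxaldehyde			X	B26
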