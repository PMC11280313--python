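name	synonyms	smiles	chem_class
quercetin	3,3',4',5,7-pentahydroxyflavone	O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12	flavonoid
kaempferol	3,4',5,7-tetrahydroxyflavone	O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12	flavonoid
myricetin	cannabiscetin	O=c1c(O)c(-c2cc(O)c(O)c(O)c2)oc2cc(O)cc(O)c12	flavonoid
fisetin	7,3',4'-flavon-3-ol	O=c1c(O)c(-c2ccc(O)c(O)c2)oc2ccc(O)cc12	flavonoid
morin	2',3,4',5,7-pentahydroxyflavone	O=c1c(O)c(-c2ccc(O)cc2O)oc2cc(O)cc(O)c12	flavonoid
galangin	3,5,7-trihydroxyflavone	O=c1c(O)c(-c2ccccc2)oc2cc(O)cc(O)c12	flavonoid
catechin	cianidanol	Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2	flavonoid
epigallocatechin gallate	EGCG	O=C(OC1Cc2c(O)cc(O)cc2OC1c1cc(O)c(O)c(O)c1)c1cc(O)c(O)c(O)c1	flavonoid
naringenin	4',5,7-trihydroxyflavanone	O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c21	flavonoid
phloridzin	phlorizin	O=C(CCc1ccc(O)cc1)c1c(O)cc(O)cc1OC1OC(CO)C(O)C(O)C1O	flavonoid
rutin	quercetin-3-rutinoside	CC1OC(OCC2OC(Oc3c(-c4ccc(O)c(O)c4)oc4cc(O)cc(O)c4c3=O)C(O)C(O)C2O)C(O)C(O)C1O	flavonoid
silybin	silibinin	COc1cc(C2Oc3ccc(C4Oc5cc(O)cc(O)c5C(=O)C4O)cc3OC2CO)ccc1O	flavonoid
taxifolin	dihydroquercetin	O=C1c2c(O)cc(O)cc2OC(c2ccc(O)c(O)c2)C1O	flavonoid
hesperetin	3',5,7-trihydroxy-4'-methoxyflavanone	COc1ccc(C2CC(=O)c3c(O)cc(O)cc3O2)cc1O	flavonoid
quercetin-3-O-glucuronide	miquelianin	O=C(O)C1OC(Oc2c(-c3ccc(O)c(O)c3)oc3cc(O)cc(O)c3c2=O)C(O)C(O)C1O	flavonoid
apigenin	4',5,7-trihydroxyflavone	O=c1cc(-c2ccc(O)cc2)oc2cc(O)cc(O)c12	flavone
luteolin	3',4',5,7-tetrahydroxyflavone	O=c1cc(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12	flavone
chrysin	5,7-dihydroxyflavone	O=c1cc(-c2ccccc2)oc2cc(O)cc(O)c12	flavone
baicalein	5,6,7-trihydroxyflavone	O=c1cc(-c2ccccc2)oc2cc(O)c(O)c(O)c12	flavone
wogonin	5,7-dihydroxy-8-methoxyflavone	COc1c(O)cc(O)c2c(=O)cc(-c3ccccc3)oc12	flavone
flavone	2-phenylchromone	O=c1cc(-c2ccccc2)oc2ccccc12	flavone
oroxylin A	5,7-dihydroxy-6-methoxyflavone	COc1c(O)cc2oc(-c3ccccc3)cc(=O)c2c1O	flavone
genistein	4',5,7-trihydroxyisoflavone	O=c1c(-c2ccc(O)cc2)coc2cc(O)cc(O)c12	isoflavone
daidzein	4',7-dihydroxyisoflavone	O=c1c(-c2ccc(O)cc2)coc2ccc(O)cc12	isoflavone
biochanin A	5,7-dihydroxy-4'-methoxyisoflavone	COc1ccc(-c2coc3cc(O)cc(O)c3c2=O)cc1	isoflavone
calycosin	3'-hydroxyformononetin	COc1ccc(-c2coc3cc(O)ccc3c2=O)cc1O	isoflavone
rhein	cassic acid	O=C(O)c1cc(O)c2c(c1)C(=O)c1cccc(O)c1C2=O	anthraquinone
emodin	frangula emodin	Cc1cc(O)c2c(c1)C(=O)c1cc(O)cc(O)c1C2=O	anthraquinone
aloe emodin	aloe-emodin	O=C1c2cccc(O)c2C(=O)c2c(O)cc(CO)cc21	anthraquinone
chrysophanol	chrysophanic acid	Cc1cc(O)c2c(c1)C(=O)c1cccc(O)c1C2=O	anthraquinone
obtusifolin	2-methoxychrysophanol	COc1c(C)cc2c(c1O)C(=O)c1cccc(O)c1C2=O	anthraquinone
gallic acid	3,4,5-trihydroxybenzoic acid	O=C(O)c1cc(O)c(O)c(O)c1	hydroxybenzoate
protocatechuic acid	3,4-dihydroxybenzoic acid	O=C(O)c1ccc(O)c(O)c1	hydroxybenzoate
vanillic acid	4-hydroxy-3-methoxybenzoic acid	COc1cc(C(=O)O)ccc1O	hydroxybenzoate
syringic acid	4-hydroxy-3,5-dimethoxybenzoic acid	COc1cc(C(=O)O)cc(OC)c1O	hydroxybenzoate
4-hydroxybenzoic acid	p-hydroxybenzoic acid	O=C(O)c1ccc(O)cc1	hydroxybenzoate
ellagic acid	benzoaric acid	O=c1oc2c(O)c(O)cc3c(=O)oc4c(O)c(O)cc1c4c23	hydroxybenzoate
cinnamic acid	trans-cinnamic acid	O=C(O)/C=C/c1ccccc1	cinnamate
p-hydroxycinnamic acid	p-coumaric acid	O=C(O)/C=C/c1ccc(O)cc1	cinnamate
ferulic acid	4-hydroxy-3-methoxycinnamic acid	COc1cc(/C=C/C(=O)O)ccc1O	cinnamate
sinapinic acid	sinapic acid	COc1cc(/C=C/C(=O)O)cc(OC)c1O	cinnamate
caffeic acid	3,4-dihydroxycinnamic acid	O=C(O)/C=C/c1ccc(O)c(O)c1	cinnamate
rosmarinic acid	labiatenic acid	O=C(/C=C/c1ccc(O)c(O)c1)OC(Cc1ccc(O)c(O)c1)C(=O)O	cinnamate
skatole	3-methylindole	Cc1c[nH]c2ccccc12	indole
indole-3-acetic acid	3-indoacetic acid|heteroauxin	O=C(O)Cc1c[nH]c2ccccc12	indole
indoxyl sulfate	indican	O=S(=O)(O)Oc1c[nH]c2ccccc12	indole
serotonin	5-hydroxytryptamine	NCCc1c[nH]c2ccc(O)cc12	indole
tryptophan	L-tryptophan	NC(Cc1c[nH]c2ccccc12)C(=O)O	indole
indole-3-carboxaldehyde	indole-3-aldehyde	O=Cc1c[nH]c2ccccc12	indole
2-oxindole	indolin-2-one	O=C1Cc2ccccc2N1	indole
3-indoleacrylic acid	indole-3-acrylic acid	O=C(O)/C=C/c1c[nH]c2ccccc12	indole
cholic acid	cholalic acid	CC(CCC(=O)O)C1CCC2C3C(O)CC4CC(O)CCC4(C)C3CC(O)C12C	colic acid
deoxycholic acid	desoxycholic acid	CC(CCC(=O)O)C1CCC2C3CCC4CC(O)CCC4(C)C3CC(O)C12C	colic acid
chenodeoxycholic acid	chenodiol	CC(CCC(=O)O)C1CCC2C3C(O)CC4CC(O)CCC4(C)C3CCC12C	colic acid
lithocholic acid	3alpha-hydroxy-5beta-cholanic acid	CC(CCC(=O)O)C1CCC2C3CCC4CC(O)CCC4(C)C3CCC12C	colic acid
progesterone	pregn-4-ene-3,20-dione	CC(=O)C1CCC2C3CCC4=CC(=O)CCC4(C)C3CCC12C	pregnenedione
pregnenolone	3beta-hydroxypregn-5-en-20-one	CC(=O)C1CCC2C3CC=C4CC(O)CCC4(C)C3CCC12C	pregnenedione
5alpha-pregnanedione	5alpha-pregnane-3,20-dione	CC(=O)C1CCC2C3CCC4CC(=O)CCC4(C)C3CCC12C	pregnenedione
17-hydroxyprogesterone	17alpha-hydroxyprogesterone	CC(=O)C1(O)CCC2C3CCC4=CC(=O)CCC4(C)C3CCC21C	pregnenedione
pregnanolone	3alpha-hydroxy-5beta-pregnan-20-one	CC(=O)C1CCC2C3CCC4CC(O)CCC4(C)C3CCC12C	pregnenedione
citric acid	2-hydroxypropane-1,2,3-tricarboxylic acid	O=C(O)CC(O)(CC(=O)O)C(=O)O	carboxylic acid
succinic acid	butanedioic acid	O=C(O)CCC(=O)O	carboxylic acid
malic acid	D-+-malic acid|hydroxybutanedioic acid	O=C(O)CC(O)C(=O)O	carboxylic acid
alpha ketoglutaric acid	2-oxoglutaric acid	O=C(O)CCC(=O)C(=O)O	carboxylic acid
cis-aconitic acid	aconitate	O=C(O)/C=C(\CC(=O)O)C(=O)O	carboxylic acid
elaidic acid	trans-9-octadecenoic acid	CCCCCCCC/C=C/CCCCCCCC(=O)O	carboxylic acid
biotin	vitamin B7|vitamin H	O=C(O)CCCCC1SCC2NC(=O)NC21	vitamin
thiamine	vitamin B1|aneurine	Cc1ncc(C[n+]2cscc2CCO)c(N)n1	vitamin
pyridoxal	vitamin B6 aldehyde	Cc1ncc(CO)c(C=O)c1O	vitamin
pyridoxamine	vitamin B6 amine	Cc1ncc(CO)c(CN)c1O	vitamin
pyridoxine	pyridoxol	Cc1ncc(CO)c(CO)c1O	vitamin
niacin	nicotinic acid|vitamin B3	O=C(O)c1cccnc1	vitamin
pantothenic acid	vitamin B5	CC(C)(CO)C(O)C(=O)NCCC(=O)O	vitamin
ascorbic acid	ascorbate|vitamin C	O=C1OC(C(O)CO)C(O)=C1O	vitamin
folic acid	vitamin B9|folate	Nc1nc2ncc(CNc3ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc3)nc2c(=O)[nH]1	vitamin
riboflavin	vitamin B2	Cc1cc2nc3c(=O)[nH]c(=O)n(CC(O)C(O)C(O)CO)c3nc2cc1C	vitamin
homovanillic acid	4-hydroxy-3-methoxyphenylacetic acid	COc1cc(CC(=O)O)ccc1O	phenolic acid
4-hydroxyphenylacetic acid	p-hydroxyphenylacetic acid	O=C(O)Cc1ccc(O)cc1	phenolic acid
4-hydroxyphenylpyruvic acid	p-hydroxyphenylpyruvate	O=C(O)C(=O)Cc1ccc(O)cc1	phenolic acid
tyramine	4-hydroxyphenethylamine	NCCc1ccc(O)cc1	phenolic amine
saccharin	benzosulfimide	O=C1NS(=O)(=O)c2ccccc21	other
arabinose	L-arabinose	OCC1OC(O)C(O)C1O	other
N-acetylglycine	aceturic acid	CC(=O)NCC(=O)O	other
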