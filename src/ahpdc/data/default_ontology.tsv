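product_code	name	classes	n_agents	atc_code
AML5	amlodipine 5mg	CCB	1	C08CA01
NIF20	nifedipine CR 20mg	CCB	1	C08CA05
CIL10	cilnidipine 10mg	CCB	1	C08CA14
CAN8	candesartan 8mg	ARB	1	C09CA06
VAL80	valsartan 80mg	ARB	1	C09CA03
TEL40	telmisartan 40mg	ARB	1	C09CA07
OLM20	olmesartan 20mg	ARB	1	C09CA08
LOS50	losartan 50mg	ARB	1	C09CA01
ENA5	enalapril 5mg	ACEI	1	C09AA02
IMI5	imidapril 5mg	ACEI	1	C09AA16
BIS2	bisoprolol 2.5mg	BETA_BLOCKER	1	C07AB07
ATE50	atenolol 50mg	BETA_BLOCKER	1	C07AB03
CAR10	carvedilol 10mg	BETA_BLOCKER	1	C07AG02
DOX2	doxazosin 2mg	ALPHA_BLOCKER	1	C02CA04
TCM2	trichlormethiazide 2mg	THIAZIDE	1	C03AA06
HCT12	hydrochlorothiazide 12.5mg	THIAZIDE	1	C03AA03
IND1	indapamide 1mg	THIAZIDE	1	C03BA11
FUR20	furosemide 20mg	LOOP	1	C03CA01
AZO30	azosemide 30mg	LOOP	1	C03CA09
SPI25	spironolactone 25mg	ALDOSTERONE_ANTAGONIST	1	C03DA01
EPL50	eplerenone 50mg	ALDOSTERONE_ANTAGONIST	1	C03DA04
MDO250	methyldopa 250mg	OTHER_AH	1	C02AB01
AMLVAL	amlodipine/valsartan	CCB;ARB	2	C09DB01
AMLTEL	amlodipine/telmisartan	CCB;ARB	2	C09DB04
AMLCAN	amlodipine/candesartan	CCB;ARB	2	C09DB07
LOSHCT	losartan/hydrochlorothiazide	ARB;THIAZIDE	2	C09DA01
VALHCT	valsartan/hydrochlorothiazide	ARB;THIAZIDE	2	C09DA03
CANHCT	candesartan/hydrochlorothiazide	ARB;THIAZIDE	2	C09DA06
TELAMLHCT	telmisartan/amlodipine/hydrochlorothiazide	CCB;ARB;THIAZIDE	3	C09DX
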