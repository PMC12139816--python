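name	formula	category
lauric acid	C12H24O2	FA
myristic acid	C14H28O2	FA
palmitic acid	C16H32O2	FA
palmitoleic acid	C16H30O2	FA
stearic acid	C18H36O2	FA
oleic acid	C18H34O2	FA
linoleic acid	C18H32O2	FA
alpha-linolenic acid	C18H30O2	FA
arachidic acid	C20H40O2	FA
arachidonic acid	C20H32O2	FA
eicosapentaenoic acid	C20H30O2	FA
behenic acid	C22H44O2	FA
docosahexaenoic acid	C22H32O2	FA
erucic acid	C22H42O2	FA
lignoceric acid	C24H48O2	FA
nervonic acid	C24H46O2	FA
2-hydroxypalmitic acid	C16H32O3	FA
12-HETE	C20H32O3	FA
palmitoylcarnitine	C23H45NO4	FA
oleamide	C18H35NO	FA
PC 30:0	C38H76NO8P	GP
PC 32:0	C40H80NO8P	GP
PC 34:1	C42H82NO8P	GP
PC 36:2	C44H84NO8P	GP
PC 36:4	C44H80NO8P	GP
PC 38:4	C46H84NO8P	GP
PE 32:0	C37H74NO8P	GP
PE 34:1	C39H76NO8P	GP
PE 36:1	C41H80NO8P	GP
PE 36:2	C41H78NO8P	GP
PE 38:4	C43H78NO8P	GP
PS 36:1	C42H80NO10P	GP
PG 34:1	C40H77O10P	GP
PG 36:2	C42H79O10P	GP
PA 34:1	C37H71O8P	GP
PA 36:2	C39H73O8P	GP
PI 34:1	C43H81O13P	GP
LPC 16:0	C24H50NO7P	GP
LPC 18:1	C26H52NO7P	GP
LPE 18:0	C23H48NO7P	GP
SM d18:1/16:0	C39H79N2O6P	SP
SM d18:1/18:1	C41H81N2O6P	SP
SM d18:1/20:0	C43H87N2O6P	SP
SM d18:1/22:0	C45H91N2O6P	SP
SM d18:1/24:0	C47H95N2O6P	SP
SM d18:1/24:1	C47H93N2O6P	SP
Cer d18:1/16:0	C34H67NO3	SP
Cer d18:0/16:0	C34H69NO3	SP
Cer d18:1/18:0	C36H71NO3	SP
Cer d18:1/20:0	C38H75NO3	SP
Cer d18:1/22:0	C40H79NO3	SP
Cer d18:1/24:0	C42H83NO3	SP
Cer d18:1/24:1	C42H81NO3	SP
sphingosine	C18H37NO2	SP
sphinganine	C18H39NO2	SP
sphingosine-1-phosphate	C18H38NO5P	SP
sphingosylphosphorylcholine	C23H49N2O5P	SP
GlcCer d18:1/16:0	C40H77NO8	SP
GlcCer d18:1/18:0	C42H81NO8	SP
GlcCer d18:1/24:1	C48H91NO8	SP
geraniol	C10H18O	PR
farnesol	C15H26O	PR
geranylgeraniol	C20H34O	PR
squalene	C30H50	PR
phytol	C20H40O	PR
retinol	C20H30O	PR
retinal	C20H28O	PR
retinoic acid	C20H28O2	PR
beta-carotene	C40H56	PR
coenzyme Q6	C39H58O4	PR
coenzyme Q8	C49H74O4	PR
coenzyme Q10	C59H90O4	PR
alpha-tocopherol	C29H50O2	PR
gamma-tocopherol	C28H48O2	PR
phylloquinone	C31H46O2	PR
menaquinone-4	C31H40O2	PR
solanesol	C45H74O	PR
vitamin D3	C27H44O	PR
vitamin D2	C28H44O	PR
farnesyl pyrophosphate	C15H28O7P2	PR
6-methylsalicylic acid	C8H8O3	PK
naringenin	C15H12O5	PK
apigenin	C15H10O5	PK
chrysin	C15H10O4	PK
kaempferol	C15H10O6	PK
quercetin	C15H10O7	PK
catechin	C15H14O6	PK
gallocatechin	C15H14O7	PK
eriodictyol	C15H12O6	PK
taxifolin	C15H12O7	PK
resveratrol	C14H12O3	PK
piceatannol	C14H12O4	PK
physcion	C16H12O5	PK
sakuranetin	C16H14O5	PK
hesperetin	C16H14O6	PK
tetracycline	C22H24N2O8	PK
erythromycin	C37H67NO13	PK
rapamycin	C51H79NO13	PK
lovastatin	C24H36O5	PK
aflatoxin B1	C17H12O6	PK
glucose	C6H12O6	NONLIPID
glucose-6-phosphate	C6H13O9P	NONLIPID
glutamine	C5H10N2O3	NONLIPID
glutamate	C5H9NO4	NONLIPID
serine	C3H7NO3	NONLIPID
citrate	C6H8O7	NONLIPID
succinate	C4H6O4	NONLIPID
lactate	C3H6O3	NONLIPID
ribose	C5H10O5	NONLIPID
inosine	C10H12N4O5	NONLIPID
hypoxanthine	C5H4N4O	NONLIPID
uridine	C9H12N2O6	NONLIPID
creatine	C4H9N3O2	NONLIPID
carnitine	C7H15NO3	NONLIPID
ATP	C10H16N5O13P3	NONLIPID
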