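name	class	carbons	double_bonds	formula
PC 32:0	PC	32	0	C40H80NO8P
PC 32:1	PC	32	1	C40H78NO8P
PC 34:0	PC	34	0	C42H84NO8P
PC 34:1	PC	34	1	C42H82NO8P
PC 34:2	PC	34	2	C42H80NO8P
PC 36:1	PC	36	1	C44H86NO8P
PC 36:2	PC	36	2	C44H84NO8P
PC 38:3	PC	38	3	C46H86NO8P
PC 38:4	PC	38	4	C46H84NO8P
PE 32:0	PE	32	0	C37H74NO8P
PE 32:1	PE	32	1	C37H72NO8P
PE 34:0	PE	34	0	C39H78NO8P
PE 34:1	PE	34	1	C39H76NO8P
PE 34:2	PE	34	2	C39H74NO8P
PE 36:1	PE	36	1	C41H80NO8P
PE 36:2	PE	36	2	C41H78NO8P
PE 38:3	PE	38	3	C43H80NO8P
PE 38:4	PE	38	4	C43H78NO8P
PS 32:0	PS	32	0	C38H74NO10P
PS 32:1	PS	32	1	C38H72NO10P
PS 34:0	PS	34	0	C40H78NO10P
PS 34:1	PS	34	1	C40H76NO10P
PS 34:2	PS	34	2	C40H74NO10P
PS 36:1	PS	36	1	C42H80NO10P
PS 36:2	PS	36	2	C42H78NO10P
PS 38:3	PS	38	3	C44H80NO10P
PS 38:4	PS	38	4	C44H78NO10P
PA 32:0	PA	32	0	C35H69O8P
PA 32:1	PA	32	1	C35H67O8P
PA 34:0	PA	34	0	C37H73O8P
PA 34:1	PA	34	1	C37H71O8P
PA 34:2	PA	34	2	C37H69O8P
PA 36:1	PA	36	1	C39H75O8P
PA 36:2	PA	36	2	C39H73O8P
PA 38:3	PA	38	3	C41H75O8P
PA 38:4	PA	38	4	C41H73O8P
PG 32:0	PG	32	0	C38H75O10P
PG 32:1	PG	32	1	C38H73O10P
PG 34:0	PG	34	0	C40H79O10P
PG 34:1	PG	34	1	C40H77O10P
PG 34:2	PG	34	2	C40H75O10P
PG 36:1	PG	36	1	C42H81O10P
PG 36:2	PG	36	2	C42H79O10P
PG 38:3	PG	38	3	C44H81O10P
PG 38:4	PG	38	4	C44H79O10P
PI 32:0	PI	32	0	C41H79O13P
PI 32:1	PI	32	1	C41H77O13P
PI 34:0	PI	34	0	C43H83O13P
PI 34:1	PI	34	1	C43H81O13P
PI 34:2	PI	34	2	C43H79O13P
PI 36:1	PI	36	1	C45H85O13P
PI 36:2	PI	36	2	C45H83O13P
PI 38:3	PI	38	3	C47H85O13P
PI 38:4	PI	38	4	C47H83O13P
SM 32:0	SM	32	0	C37H77N2O6P
SM 32:1	SM	32	1	C37H75N2O6P
SM 34:0	SM	34	0	C39H81N2O6P
SM 34:1	SM	34	1	C39H79N2O6P
SM 34:2	SM	34	2	C39H77N2O6P
SM 36:1	SM	36	1	C41H83N2O6P
SM 36:2	SM	36	2	C41H81N2O6P
SM 38:3	SM	38	3	C43H83N2O6P
SM 38:4	SM	38	4	C43H81N2O6P
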