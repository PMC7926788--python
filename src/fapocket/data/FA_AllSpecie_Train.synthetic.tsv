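# synthetic stand-in for a curated FA-binding structure table
pdb_id	chain	ligand_code	species	label
15GK	D	DHA	Equus melanogaster	1
19TI	C	VCA	Sus melanogaster	1
1FYA	A	ACD	Danio cerevisiae	1
1LT3	B		Sus norvegicus	0
1N96	A	OLA	Homo melanogaster	1
1PE4	A	DAO	Bos norvegicus	1
1Q06	C		Arabidopsis norvegicus	0
25ET	D	OLA	Bos norvegicus	1
26JB	C		Danio cerevisiae	0
2D67	C	OLA	Gallus cerevisiae	1
2DD7	D	DAO	Homo norvegicus	1
2ECV	A		Canis thaliana	0
2IUS	B		Mus norvegicus	0
2IW2	B		Drosophila norvegicus	0
2PSW	B	OLA	Saccharomyces thaliana	1
2WZI	B	PAM	Bos cerevisiae	1
2XXJ	C	LNL	Sus melanogaster	1
30YJ	D	OLA	Rattus melanogaster	1
33RI	D	STE	Bos thaliana	1
3K0M	C	LAU	Saccharomyces norvegicus	1
3LPT	A	STE	Gallus thaliana	1
3WS4	A	HXA	Danio melanogaster	1
3Z7W	D		Rattus norvegicus	0
3ZLM	C		Equus cerevisiae	0
41JV	B		Canis norvegicus	0
42NW	C	OLA	Danio norvegicus	1
44EQ	D	OLA	Mus cerevisiae	1
4AQI	B		Drosophila thaliana	0
4GFI	D		Canis thaliana	0
4HCP	B		Mus thaliana	0
4LUB	C	ELA	Saccharomyces melanogaster	1
4WXZ	C		Rattus thaliana	0
50S9	C		Canis melanogaster	0
52EK	D		Drosophila melanogaster	0
57CG	B		Rattus cerevisiae	0
58Y3	D	DKA	Danio thaliana	1
5KSI	A	PLM	Xenopus melanogaster	1
5NM4	A	MYR	Sus melanogaster	1
5QCN	D	LAU	Drosophila cerevisiae	1
5XL1	D		Bos norvegicus	0
5XUL	C	DAO	Equus thaliana	1
6071	B		Gallus melanogaster	0
6507	D	DHA	Canis cerevisiae	1
6N4H	C	OLA	Saccharomyces norvegicus	1
6QTY	D	EPA	Xenopus norvegicus	1
6VWL	C		Rattus thaliana	0
750N	A		Bos melanogaster	0
77BK	D	PAM	Arabidopsis cerevisiae	1
7B6U	B	DAO	Xenopus thaliana	1
7BS4	B	DHA	Arabidopsis cerevisiae	1
7KIY	C	DHA	Equus cerevisiae	1
7L48	C		Sus cerevisiae	0
7N9N	B		Saccharomyces thaliana	0
7OFQ	A		Bos thaliana	0
84SM	A	EPA	Xenopus cerevisiae	1
8BM1	D	EPA	Rattus norvegicus	1
8H7L	D		Mus melanogaster	0
8OMA	C	DKA	Arabidopsis thaliana	1
8SQE	A	STE	Rattus norvegicus	1
8XWX	D	VCA	Homo cerevisiae	1
90CP	C	ACD	Equus norvegicus	1
94C1	A	EPA	Sus thaliana	1
976V	A	ELA	Gallus norvegicus	1
98NH	C	ELA	Saccharomyces cerevisiae	1
9AWQ	C	DAO	Canis thaliana	1
9J1H	D	STE	Homo thaliana	1
9KGU	C		Arabidopsis melanogaster	0
9NLA	D	OLA	Canis thaliana	1
9RRR	A	DKA	Equus melanogaster	1
9THY	D	LAU	Sus thaliana	1
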