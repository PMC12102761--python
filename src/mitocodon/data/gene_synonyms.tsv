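synonym	canonical
ATP6	ATP6
ATPASE6	ATP6
ATPASE 6	ATP6
ATP SYNTHASE F0 SUBUNIT 6	ATP6
ATP SYNTHASE SUBUNIT 6	ATP6
ATP8	ATP8
ATPASE8	ATP8
ATPASE 8	ATP8
ATP SYNTHASE F0 SUBUNIT 8	ATP8
ATP SYNTHASE SUBUNIT 8	ATP8
COX1	COX1
COI	COX1
CO1	COX1
COXI	COX1
MT-CO1	COX1
CYTOCHROME C OXIDASE SUBUNIT 1	COX1
CYTOCHROME C OXIDASE SUBUNIT I	COX1
COX2	COX2
COII	COX2
CO2	COX2
COXII	COX2
MT-CO2	COX2
CYTOCHROME C OXIDASE SUBUNIT 2	COX2
CYTOCHROME C OXIDASE SUBUNIT II	COX2
COX3	COX3
COIII	COX3
CO3	COX3
COXIII	COX3
MT-CO3	COX3
CYTOCHROME C OXIDASE SUBUNIT 3	COX3
CYTOCHROME C OXIDASE SUBUNIT III	COX3
CYTB	CYTB
COB	CYTB
CYT B	CYTB
MT-CYB	CYTB
CYTOCHROME B	CYTB
NAD1	NAD1
ND1	NAD1
NADH1	NAD1
NADH DEHYDROGENASE SUBUNIT 1	NAD1
NAD2	NAD2
ND2	NAD2
NADH2	NAD2
NADH DEHYDROGENASE SUBUNIT 2	NAD2
NAD3	NAD3
ND3	NAD3
NADH3	NAD3
NADH DEHYDROGENASE SUBUNIT 3	NAD3
NAD4	NAD4
ND4	NAD4
NADH4	NAD4
NADH DEHYDROGENASE SUBUNIT 4	NAD4
NAD4L	NAD4L
ND4L	NAD4L
NADH4L	NAD4L
NADH DEHYDROGENASE SUBUNIT 4L	NAD4L
NAD5	NAD5
ND5	NAD5
NADH5	NAD5
NADH DEHYDROGENASE SUBUNIT 5	NAD5
NAD6	NAD6
ND6	NAD6
NADH6	NAD6
NADH DEHYDROGENASE SUBUNIT 6	NAD6
12S RIBOSOMAL RNA	srRNA
12S RRNA	srRNA
RRNS	srRNA
S-RRNA	srRNA
SRRNA	srRNA
SMALL SUBUNIT RIBOSOMAL RNA	srRNA
16S RIBOSOMAL RNA	lrRNA
16S RRNA	lrRNA
RRNL	lrRNA
L-RRNA	lrRNA
LRRNA	lrRNA
LARGE SUBUNIT RIBOSOMAL RNA	lrRNA
D-LOOP	CR
D LOOP	CR
CONTROL REGION	CR
CR	CR
PUTATIVE CONTROL REGION	CR
OL	OL
O-L	OL
L-STRAND ORIGIN	OL
ORIGIN OF L-STRAND REPLICATION	OL
ORIGIN OF LIGHT STRAND REPLICATION	OL
REPLICATION ORIGIN OF THE LIGHT STRAND	OL
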