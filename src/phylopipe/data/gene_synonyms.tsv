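# gene-label synonym table: <synonym><TAB><canonical>
# lookup keys are case-folded; edit freely to extend the mapping
coi	COX1
co1	COX1
cox1	COX1
coxi	COX1
cox i	COX1
cytochrome c oxidase subunit i	COX1
cytochrome c oxidase subunit 1	COX1
cytochrome oxidase subunit i	COX1
cytochrome oxidase subunit 1	COX1
coii	COX2
co2	COX2
cox2	COX2
coxii	COX2
cytochrome c oxidase subunit ii	COX2
cytochrome c oxidase subunit 2	COX2
coiii	COX3
co3	COX3
cox3	COX3
coxiii	COX3
cytochrome c oxidase subunit iii	COX3
cytochrome c oxidase subunit 3	COX3
cytb	CYTB
cob	CYTB
cyt b	CYTB
cytochrome b	CYTB
nd1	ND1
nadh1	ND1
nadh dehydrogenase subunit 1	ND1
nd2	ND2
nadh2	ND2
nadh dehydrogenase subunit 2	ND2
nd3	ND3
nadh3	ND3
nadh dehydrogenase subunit 3	ND3
nd4	ND4
nadh4	ND4
nadh dehydrogenase subunit 4	ND4
nd4l	ND4L
nadh4l	ND4L
nadh dehydrogenase subunit 4l	ND4L
nd5	ND5
nadh5	ND5
nadh dehydrogenase subunit 5	ND5
nd6	ND6
nadh6	ND6
nadh dehydrogenase subunit 6	ND6
atp6	ATP6
atpase6	ATP6
atp synthase f0 subunit 6	ATP6
atp8	ATP8
atpase8	ATP8
atp synthase f0 subunit 8	ATP8
12s	RRNS
12s rrna	RRNS
12s ribosomal rna	RRNS
rrns	RRNS
s-rrna	RRNS
small subunit ribosomal rna	RRNS
16s	RRNL
16s rrna	RRNL
16s ribosomal rna	RRNL
rrnl	RRNL
l-rrna	RRNL
large subunit ribosomal rna	RRNL
18s	18S
18s rrna	18S
18s ribosomal rna	18S
28s	28S
28s rrna	28S
28s ribosomal rna	28S
5.8s	5.8S
5.8s rrna	5.8S
its1	ITS1
internal transcribed spacer 1	ITS1
its2	ITS2
internal transcribed spacer 2	ITS2
ef1a	EF1A
ef-1a	EF1A
ef1-alpha	EF1A
elongation factor 1-alpha	EF1A
elongation factor 1 alpha	EF1A
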