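# Gene-name synonym table: raw label (case-insensitive) -> canonical name.
# Edit to extend; canonical names always map to themselves.
coi	cox1
co1	cox1
cox1	cox1
coxi	cox1
cytochrome c oxidase subunit i	cox1
cytochrome c oxidase subunit 1	cox1
coii	cox2
co2	cox2
coxii	cox2
cytochrome c oxidase subunit ii	cox2
cytochrome c oxidase subunit 2	cox2
coiii	cox3
co3	cox3
coxiii	cox3
cytochrome c oxidase subunit iii	cox3
cytochrome c oxidase subunit 3	cox3
cytb	cob
cob	cob
cytochrome b	cob
atpase6	atp6
atp synthase f0 subunit 6	atp6
atpase8	atp8
atp synthase f0 subunit 8	atp8
nd1	nad1
nadh1	nad1
nadh dehydrogenase subunit 1	nad1
nd2	nad2
nadh2	nad2
nadh dehydrogenase subunit 2	nad2
nd3	nad3
nadh3	nad3
nadh dehydrogenase subunit 3	nad3
nd4	nad4
nadh4	nad4
nadh dehydrogenase subunit 4	nad4
nd4l	nad4L
nadh4l	nad4L
nadh dehydrogenase subunit 4l	nad4L
nd5	nad5
nadh5	nad5
nadh dehydrogenase subunit 5	nad5
nd6	nad6
nadh6	nad6
nadh dehydrogenase subunit 6	nad6
12s	rrnS
12s rrna	rrnS
12s ribosomal rna	rrnS
s-rrna	rrnS
srrna	rrnS
small subunit ribosomal rna	rrnS
16s	rrnL
16s rrna	rrnL
16s ribosomal rna	rrnL
l-rrna	rrnL
lrrna	rrnL
large subunit ribosomal rna	rrnL
trna-ala	trnA
trna-cys	trnC
trna-asp	trnD
trna-glu	trnE
trna-phe	trnF
trna-gly	trnG
trna-his	trnH
trna-ile	trnI
trna-lys	trnK
trna-leu	trnL
trnl	trnL
trna-met	trnM
trna-asn	trnN
trna-pro	trnP
trna-gln	trnQ
trna-arg	trnR
trna-ser	trnS
trns	trnS
trna-thr	trnT
trna-val	trnV
trna-trp	trnW
trna-tyr	trnY
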