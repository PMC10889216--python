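# Mitochondrial gene orders of 15 planorbid snails (one genome per line:
# id, then signed gene tokens; '+' = major strand, '-' = minor strand).
#
# Provenance of each arrangement type:
#   type E (OR684570, Polypylis sp. TS-2018): read directly from the
#     published annotation table (coordinates and strands).
#   type D (OX421510, Anisus vortex): type E with rrnS restored to the
#     minor-strand state (undoing the rrnS reverse transposition reported
#     for Polypylis and Gyraulus).
#   type F (MW357851, Gyraulus sp.): type E plus the reverse transposition
#     of trnQ reported only for Gyraulus (orientation flip at its junction).
#   type B (Bulinus truncatus, the six non-tenagophila Biomphalaria, and
#     both Planorbella): type E with trnW and trnC restored to their common
#     gastropod positions (trnC between trnD and trnF, trnW between trnY
#     and trnG) and rrnS on the minor strand.
#   type A (Bulinus globosus/nasutus/ugandae): type B with trnD moved out
#     of the cob|trnC junction.  The published comparison does not state
#     trnD's position in type A; this file places it between cox2 and trnY
#     (synthetic choice, fixed).  Event detection is insensitive to the
#     choice of source junction.
#   type C (EF433576, Biomphalaria tenagophila): type B with seven tRNAs
#     (trnE, trnL2, trnM, trnN, trnQ, trnR, trnS2) orientation-flipped
#     (reverse transpositions at their junctions).
#
# type A
MK414453 +nad6 +nad5 +nad1 +nad4L +cob +trnC +trnF +cox2 +trnD +trnY +trnW +trnG +trnH -trnQ -trnL2 -atp8 -trnN -atp6 -trnR -trnE -rrnS -trnM -nad3 -trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
MK414450 +nad6 +nad5 +nad1 +nad4L +cob +trnC +trnF +cox2 +trnD +trnY +trnW +trnG +trnH -trnQ -trnL2 -atp8 -trnN -atp6 -trnR -trnE -rrnS -trnM -nad3 -trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
MK414451 +nad6 +nad5 +nad1 +nad4L +cob +trnC +trnF +cox2 +trnD +trnY +trnW +trnG +trnH -trnQ -trnL2 -atp8 -trnN -atp6 -trnR -trnE -rrnS -trnM -nad3 -trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
# type B
MK414449 +nad6 +nad5 +nad1 +nad4L +cob +trnD +trnC +trnF +cox2 +trnY +trnW +trnG +trnH -trnQ -trnL2 -atp8 -trnN -atp6 -trnR -trnE -rrnS -trnM -nad3 -trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
MG431964 +nad6 +nad5 +nad1 +nad4L +cob +trnD +trnC +trnF +cox2 +trnY +trnW +trnG +trnH -trnQ -trnL2 -atp8 -trnN -atp6 -trnR -trnE -rrnS -trnM -nad3 -trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
NC_005439 +nad6 +nad5 +nad1 +nad4L +cob +trnD +trnC +trnF +cox2 +trnY +trnW +trnG +trnH -trnQ -trnL2 -atp8 -trnN -atp6 -trnR -trnE -rrnS -trnM -nad3 -trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
MG431962 +nad6 +nad5 +nad1 +nad4L +cob +trnD +trnC +trnF +cox2 +trnY +trnW +trnG +trnH -trnQ -trnL2 -atp8 -trnN -atp6 -trnR -trnE -rrnS -trnM -nad3 -trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
MF480756 +nad6 +nad5 +nad1 +nad4L +cob +trnD +trnC +trnF +cox2 +trnY +trnW +trnG +trnH -trnQ -trnL2 -atp8 -trnN -atp6 -trnR -trnE -rrnS -trnM -nad3 -trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
MG431963 +nad6 +nad5 +nad1 +nad4L +cob +trnD +trnC +trnF +cox2 +trnY +trnW +trnG +trnH -trnQ -trnL2 -atp8 -trnN -atp6 -trnR -trnE -rrnS -trnM -nad3 -trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
KY514384 +nad6 +nad5 +nad1 +nad4L +cob +trnD +trnC +trnF +cox2 +trnY +trnW +trnG +trnH -trnQ -trnL2 -atp8 -trnN -atp6 -trnR -trnE -rrnS -trnM -nad3 -trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
MW889961 +nad6 +nad5 +nad1 +nad4L +cob +trnD +trnC +trnF +cox2 +trnY +trnW +trnG +trnH -trnQ -trnL2 -atp8 -trnN -atp6 -trnR -trnE -rrnS -trnM -nad3 -trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
# type C
EF433576 +nad6 +nad5 +nad1 +nad4L +cob +trnD +trnC +trnF +cox2 +trnY +trnW +trnG +trnH +trnQ +trnL2 -atp8 +trnN -atp6 +trnR +trnE -rrnS +trnM -nad3 +trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
# type D
OX421510 +nad6 +nad5 +nad1 +nad4L +trnW +trnC +cob +trnD +trnF +cox2 +trnY +trnG +trnH -trnQ -trnL2 -atp8 -trnN -atp6 -trnR -trnE -rrnS -trnM -nad3 -trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
# type E
OR684570 +nad6 +nad5 +nad1 +nad4L +trnW +trnC +cob +trnD +trnF +cox2 +trnY +trnG +trnH -trnQ -trnL2 -atp8 -trnN -atp6 -trnR -trnE +rrnS -trnM -nad3 -trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
# type F
MW357851 +nad6 +nad5 +nad1 +nad4L +trnW +trnC +cob +trnD +trnF +cox2 +trnY +trnG +trnH +trnQ -trnL2 -atp8 -trnN -atp6 -trnR -trnE +rrnS -trnM -nad3 -trnS2 +trnS1 +nad4 -trnT -cox3 +trnI +nad2 +trnK +cox1 +trnV +rrnL +trnL1 +trnA +trnP
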