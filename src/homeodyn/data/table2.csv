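family,human,chimpanzee,macaque,mouse,rat,cow,pig,horse,dog,chicken,frog
Leutx,P,P,P,-,-,-,-,-,-,-,-
Obox,-,-,-,P,P,-,-,-,-,-,-
Crxos1,-,-,-,P,P,-,-,-,-,-,-
Gm5585,-,-,-,P,P,-,-,-,-,-,-
Gm7235,-,-,-,P,P,-,-,-,-,-,-
Msx3,-,-,-,P,P,-,P,P,-,-,-
Ventx,P,P,P,-,-,-,-,-,P,P,--
Argfx,P,P,P,-,-,P,-,P,-,-,-
Dprx,P,P,P,-,-,P,-,P,P,-,-
Shox,P,P,P,-,-,P,P,-,P,P,P
Rax2,P,P,P,-,-,P,-,-,P,P,P
LOC647589,P,P,P,-,-,P,P,P,P,-,-
Tprx1,P,P,P,-,-,-,-,-,P,-,-
Nanognb,P,P,P,-,-,-,-,P,P,-,-
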