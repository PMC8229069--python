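label	species	catalog	origin
D. antarctica KEW-0522816	Deschampsia antarctica E. Desv.	KEW-0522816	Falkland Is., St. Georgia
D. antarctica KEW-0661919	Deschampsia antarctica E. Desv.	KEW-0661919	Falkland Is., Weddle
D. antarctica KEW-0521613	Deschampsia antarctica E. Desv.	KEW-0521613	Falkland Is., St. Georgia
D. cespitosa PI-562652	Deschampsia cespitosa ssp. beringensis (Hulten) W.E. Lawr.	PI-562652	Alaska, USA
D. cespitosa PI-371724	Deschampsia cespitosa (L.) P. Beauv.	PI-371724	Alaska, Valdez, USA
D. cespitosa PI-577069	Deschampsia cespitosa (L.) P. Beauv.	PI-577069	Great Britain
D. danthonioides	Deschampsia danthonioides (Trin.) Munro	W6-39054	Washington, USA
D. elongata	Deschampsia elongata (Hook.) Munro	PI-665545	Oregon, USA
D. flexuosa	Deschampsia flexuosa (L.) Trin.	PI-577075	Wales, UK
D. parvula	Deschampsia parvula (Hook.f.) E. Desv.	KEW-0661849	Falkland Is.
D. sukatschewii	Deschampsia sukatschewii (Popl.) Roshev	78	Altai Mountains, RF
H. pubescens	Helictotrichon pubescens (Huds.) Pilg.	KEW-065160	England, UK
K. macrantha	Kolleria macrantha (Ledeb.) Schult.	KEW-0096838	Greece
T. phleoides	Tricetum phleoides (d'Urv.) Kunth.	KEW-0662385	Falkland Is.
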