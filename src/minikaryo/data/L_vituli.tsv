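E-cytb-S1-S2-R-nad4L-P-atp8	3052	1887	1160	0
rrnS-C-atp6-N	2656	1473	1179	0
I-cox1	2752	1566	1151	0
Y-cox2-nad6	2369	1218	1141	0
prrnS-prrnL-cox3-W-A	2086	893	686	435
~Q-~nad1-~T-G-nad3	2722	1417	1296	0
prrnS#2-pcox2-D-L1#2-nad2	2709	1133	1112	416
K-nad4	2469	1286	1182	0
H-nad5-F-L2	3000	1830	1170	0
M-L1-rrnL-V	2443	1310	1133	0
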