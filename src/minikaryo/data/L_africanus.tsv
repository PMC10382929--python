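E-cytb-S1-S2-R-nad4L-P-atp8	3769	1874	1892	0
rrnS-C-patp8-atp6-N	3653	1470	2011	170
I-cox1	3725	1599	2126	0
D-Y-cox2-nad6	3333	1303	2026	0
H#2-cox3-W-A	3486	965	2519	0
~Q-~nad1-~T-G-nad3	3371	1409	1944	0
M#2-L1#2-nad2	3102	1147	1940	0
K-nad4	3472	1266	2170	0
H-nad5-F-L2	3915	1829	2085	0
M-L1-rrnL-V	3444	1295	2149	0
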