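E-cytb-S1-S2-R-nad4L-P-atp8#2
rrnS-C-atp8-atp6-N
I-cox1
D-Y-cox2-nad6
cox3-W-A
~Q-~nad1-~T-G-nad3
L1#2-nad2
K-nad4
H-nad5-F-L2
M-L1-rrnL-V
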