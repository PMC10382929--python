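E-cytb-S1-S2
rrnS-C
atp8-atp6-N
I-cox1-L2
D-Y-cox2-nad6
R-nad4L-P-cox3-A
~Q-~nad1-~T-G-nad3-W
nad2
K-nad4
H-nad5-F
M-L1-rrnL-V
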