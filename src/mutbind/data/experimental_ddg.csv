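variant,ddg_kj_mol,esd_kj_mol
N65R,2.1,
N70G,-0.6,
S95R,2.1,
N96F,-0.2,
N96W,-3.9,0.2
K115Y,0.7,
T166M,2.0,
T166Y,2.5,
H222R,-0.1,0.2
N96W+H222R,-5.0,0.2
N70G+S95R,1.5,
N70G+H222R,-0.3,
S95R+H222R,1.5,
N70G+S95R+H222R,0.5,0.1
Y66L,0.0,
S71E,1.6,
H222D,2.0,
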