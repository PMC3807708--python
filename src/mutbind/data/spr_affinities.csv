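variant,ka_per_M_s,kd_per_s,Kd_M,n_replicates,esd_M
WT,1.24e6,3.78e-2,30.8e-9,14,1.5e-9
N65R,0.882e6,6.28e-2,71.2e-9,1,
N70G,1.12e6,2.64e-2,23.6e-9,1,
S95R,0.650e6,4.54e-2,69.8e-9,2,
N96F,1.01e6,2.83e-2,28.0e-9,1,
N96W,1.43e6,0.909e-2,6.34e-9,4,0.49e-9
K115Y,0.979e6,3.91e-2,39.9e-9,1,
T166M,0.933e6,6.39e-2,68.5e-9,1,
T166Y,0.940e6,7.82e-2,83.1e-9,1,
H222R,1.19e6,3.49e-2,29.4e-9,6,1.9e-9
N96W+H222R,2.40e6,1.00e-2,4.16e-9,3,0.37e-9
N70G+S95R,0.889e6,4.94e-2,55.9e-9,2,
N70G+H222R,1.46e6,3.91e-2,26.9e-9,2,
S95R+H222R,1.05e6,5.90e-2,56.3e-9,2,
N70G+S95R+H222R,1.09e6,4.01e-2,37.0e-9,5,2.1e-9
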