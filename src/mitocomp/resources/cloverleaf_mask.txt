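# Default tRNA cloverleaf structure mask for a 71-column alignment
# (acceptor stem 7 bp, DHU stem 4 bp / loop 8 nt, anticodon stem 5 bp /
# loop 7 nt, variable region 4 nt, T-psi-C stem 5 bp / loop 7 nt).
# Format: start end label (1-based inclusive column ranges).
1 7 AA_stem
8 9 connector
10 13 DHU_arm
14 21 DHU_loop
22 25 DHU_arm
26 26 connector
27 31 AC_arm
32 38 AC_loop
39 43 AC_arm
44 47 connector
48 52 TpsiC_arm
53 59 TpsiC_loop
60 64 TpsiC_arm
65 71 AA_stem
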