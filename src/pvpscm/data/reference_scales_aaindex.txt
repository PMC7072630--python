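H KOEP990101
D Alpha-helix propensity derived from designed sequences (Koehl-Levitt, 1999)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   -0.04   -0.30    0.25    0.27    0.57   -0.02   -0.33    1.24   -0.11   -0.26
   -0.38   -0.18   -0.09   -0.01    0.00    0.15    0.39    0.21    0.05   -0.06
//
H SIDECHAIN
D Side-chain size scale (published side-chain values; synthetic accession, not in AAindex)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
      15     101      58      59      47      72      73       1      82      57
      57      73      75      91      42      31      45     130     107      43
//
H WOLR790101
D Hydrophobicity index (Wolfenden et al., 1979)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.12   -2.55   -0.83   -0.83    0.59   -0.78   -0.92    1.20   -0.93    1.16
    1.18   -0.80    0.55    0.67    0.54   -0.05   -0.02   -0.19   -0.23    1.13
//
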