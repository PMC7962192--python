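H HYDROPATHY_KD
D Kyte-Doolittle hydropathy index
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.80   -4.50   -3.50   -3.50    2.50   -3.50   -3.50   -0.40   -3.20    4.50
     3.80   -3.90    1.90    2.80   -1.60   -0.80   -0.70   -0.90   -1.30    4.20
//
H RESIDUE_MASS
D Amino acid residue molecular weight (Da)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    89.10  174.20  132.10  133.10  121.20  146.20  147.10   75.10  155.20  131.20
   131.20  146.20  149.20  165.20  115.10  105.10  119.10  204.20  181.20  117.10
//
H RESIDUE_VOLUME
D Residue side-chain volume (A^3, Zamyatnin-style scale)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    88.60  173.40  114.10  111.10  108.50  143.80  138.40   60.10  153.20  166.70
   166.70  168.60  162.90  189.90  112.70   89.00  116.10  227.80  193.60  140.00
//
H POLARITY_GRANTHAM
D Grantham polarity
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     8.10   10.50   11.60   13.00    5.50   10.50   12.30    9.00   10.40    5.20
     4.90   11.30    5.70    5.20    8.00    9.20    8.60    5.40    6.20    5.90
//
H ISOELECTRIC_POINT
D Isoelectric point of the free amino acid
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     6.00   10.76    5.41    2.77    5.07    5.65    3.22    5.97    7.59    6.02
     5.98    9.74    5.74    5.48    6.30    5.68    5.60    5.89    5.66    5.96
//
H NET_CHARGE_PH7
D Approximate side-chain net charge at pH 7
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.00    1.00    0.00   -1.00    0.00    0.00   -1.00    0.00    0.10    0.00
     0.00    1.00    0.00    0.00    0.00    0.00    0.00    0.00    0.00    0.00
//
H AROMATICITY
D Aromatic side-chain indicator (His counted half)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.00    0.00    0.00    0.00    0.00    0.00    0.00    0.00    0.50    0.00
     0.00    0.00    0.00    1.00    0.00    0.00    0.00    1.00    1.00    0.00
//
H ALIPHATICITY
D Aliphatic side-chain indicator
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.00    0.00    0.00    0.00    0.00    0.00    0.00    1.00    0.00    1.00
     1.00    0.00    0.00    0.00    1.00    0.00    0.00    0.00    0.00    1.00
//
H HBOND_DONORS
D Side-chain hydrogen-bond donor count
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.00    4.00    2.00    0.00    1.00    2.00    0.00    0.00    1.00    0.00
     0.00    3.00    0.00    0.00    0.00    1.00    1.00    1.00    1.00    0.00
//
H HBOND_ACCEPTORS
D Side-chain hydrogen-bond acceptor count
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.00    0.00    2.00    2.00    0.00    2.00    2.00    0.00    1.00    0.00
     0.00    0.00    1.00    0.00    0.00    1.00    1.00    0.00    1.00    0.00
//
H HELIX_CHOUFASMAN
D Chou-Fasman alpha-helix propensity
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.42    0.98    0.67    1.01    0.70    1.11    1.51    0.57    1.00    1.08
     1.21    1.16    1.45    1.13    0.57    0.77    0.83    1.08    0.69    1.06
//
H SHEET_CHOUFASMAN
D Chou-Fasman beta-sheet propensity
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.83    0.93    0.89    0.54    1.19    1.10    0.37    0.75    0.87    1.60
     1.30    0.74    1.05    1.38    0.55    0.75    1.19    1.37    1.47    1.70
//
H TURN_CHOUFASMAN
D Chou-Fasman beta-turn propensity
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.66    0.95    1.56    1.46    1.19    0.98    0.74    1.56    0.95    0.47
     0.59    1.01    0.60    0.60    1.52    1.43    0.96    0.96    1.14    0.50
//
H HYDROPHILICITY_HW
D Hopp-Woods hydrophilicity
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    -0.50    3.00    0.20    3.00   -1.00    0.20    3.00    0.00   -0.50   -1.80
    -1.80    3.00   -1.30   -2.50    0.00    0.30   -0.40   -3.40   -2.30   -1.50
//
H SURFACE_AREA
D Accessible surface area of residue X in Gly-X-Gly (A^2)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   115.00  225.00  160.00  150.00  135.00  180.00  190.00   75.00  195.00  175.00
   170.00  200.00  185.00  210.00  145.00  115.00  140.00  255.00  230.00  155.00
//
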