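BASIS "ao basis" SPHERICAL PRINT
#BASIS SET: (4s,1p) -> [2s,1p]
H    S
      1.301000E+01           1.968500E-02           0.000000E+00
      1.962000E+00           1.379770E-01           0.000000E+00
      4.446000E-01           4.781480E-01           0.000000E+00
      1.220000E-01           5.012400E-01           1.000000E+00
H    P
      7.270000E-01           1.0000000
#BASIS SET: (9s,4p,1d) -> [3s,2p,1d]
C    S
      6.665000E+03           6.920000E-04          -1.460000E-04           0.000000E+00
      1.000000E+03           5.329000E-03          -1.154000E-03           0.000000E+00
      2.280000E+02           2.707700E-02          -5.725000E-03           0.000000E+00
      6.471000E+01           1.017180E-01          -2.331200E-02           0.000000E+00
      2.106000E+01           2.747400E-01          -6.395500E-02           0.000000E+00
      7.495000E+00           4.485640E-01          -1.499810E-01           0.000000E+00
      2.797000E+00           2.850740E-01          -1.272620E-01           0.000000E+00
      5.215000E-01           1.520400E-02           5.445290E-01           0.000000E+00
      1.596000E-01          -3.191000E-03           5.804960E-01           1.000000E+00
C    P
      9.439000E+00           3.810900E-02           0.000000E+00
      2.002000E+00           2.094800E-01           0.000000E+00
      5.456000E-01           5.085570E-01           0.000000E+00
      1.517000E-01           4.688420E-01           1.000000E+00
C    D
      5.500000E-01           1.0000000
#BASIS SET: (9s,4p,1d) -> [3s,2p,1d]
N    S
      9.046000E+03           7.000000E-04          -1.530000E-04           0.000000E+00
      1.357000E+03           5.389000E-03          -1.208000E-03           0.000000E+00
      3.093000E+02           2.740600E-02          -5.992000E-03           0.000000E+00
      8.773000E+01           1.032070E-01          -2.454400E-02           0.000000E+00
      2.856000E+01           2.787230E-01          -6.745900E-02           0.000000E+00
      1.021000E+01           4.485400E-01          -1.580780E-01           0.000000E+00
      3.838000E+00           2.782380E-01          -1.218310E-01           0.000000E+00
      7.466000E-01           1.544000E-02           5.490030E-01           0.000000E+00
      2.248000E-01          -2.864000E-03           5.788150E-01           1.000000E+00
N    P
      1.355000E+01           3.991900E-02           0.000000E+00
      2.917000E+00           2.171690E-01           0.000000E+00
      7.973000E-01           5.103190E-01           0.000000E+00
      2.185000E-01           4.622140E-01           1.000000E+00
N    D
      8.170000E-01           1.0000000
#BASIS SET: (9s,4p,1d) -> [3s,2p,1d]
O    S
      1.172000E+04           7.100000E-04          -1.600000E-04           0.000000E+00
      1.759000E+03           5.470000E-03          -1.263000E-03           0.000000E+00
      4.008000E+02           2.783700E-02          -6.267000E-03           0.000000E+00
      1.137000E+02           1.048000E-01          -2.571600E-02           0.000000E+00
      3.703000E+01           2.830620E-01          -7.092400E-02           0.000000E+00
      1.327000E+01           4.487190E-01          -1.654110E-01           0.000000E+00
      5.025000E+00           2.709520E-01          -1.169550E-01           0.000000E+00
      1.013000E+00           1.545800E-02           5.573680E-01           0.000000E+00
      3.023000E-01          -2.585000E-03           5.727590E-01           1.000000E+00
O    P
      1.770000E+01           4.301800E-02           0.000000E+00
      3.854000E+00           2.289130E-01           0.000000E+00
      1.046000E+00           5.087280E-01           0.000000E+00
      2.753000E-01           4.605310E-01           1.000000E+00
O    D
      1.185000E+00           1.0000000
END
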