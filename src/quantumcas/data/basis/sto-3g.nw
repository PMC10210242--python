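BASIS "ao basis" SPHERICAL PRINT
#BASIS SET: (3s) -> [1s]
H    S
      0.3425250914E+01       0.1543289673E+00
      0.6239137298E+00       0.5353281423E+00
      0.1688554040E+00       0.4446345422E+00
#BASIS SET: (6s,3p) -> [2s,1p]
C    S
      0.7161683735E+02       0.1543289673E+00
      0.1304509632E+02       0.5353281423E+00
      0.3530512160E+01       0.4446345422E+00
C    SP
      0.2941249355E+01      -0.9996722919E-01       0.1559162750E+00
      0.6834830964E+00       0.3995128261E+00       0.6076837186E+00
      0.2222899159E+00       0.7001154689E+00       0.3919573931E+00
#BASIS SET: (6s,3p) -> [2s,1p]
N    S
      0.9910616896E+02       0.1543289673E+00
      0.1805231239E+02       0.5353281423E+00
      0.4885660238E+01       0.4446345422E+00
N    SP
      0.3780455879E+01      -0.9996722919E-01       0.1559162750E+00
      0.8784966449E+00       0.3995128261E+00       0.6076837186E+00
      0.2857143744E+00       0.7001154689E+00       0.3919573931E+00
#BASIS SET: (6s,3p) -> [2s,1p]
O    S
      0.1307093214E+03       0.1543289673E+00
      0.2380886605E+02       0.5353281423E+00
      0.6443608313E+01       0.4446345422E+00
O    SP
      0.5033151319E+01      -0.9996722919E-01       0.1559162750E+00
      0.1169596125E+01       0.3995128261E+00       0.6076837186E+00
      0.3803889600E+00       0.7001154689E+00       0.3919573931E+00
END
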