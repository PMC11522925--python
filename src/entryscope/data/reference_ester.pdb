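REMARK   Reference geometry anchoring the si/re face convention: the
REMARK   serine gamma-oxygen (atom 2) sits on the SI face of the ester
REMARK   plane through C1/O1/O2 (atoms 6-8).  Mirroring through the
REMARK   plane yields the re label.
ATOM      1  CA  SER A   1      -4.500   0.000   0.000  1.00  0.00           C
ATOM      2  OG  SER A   1      -3.000   0.000   0.000  1.00  0.00           O
ATOM      3  HN1 GLY A   2       1.600   2.800   0.000  1.00  0.00           H
ATOM      4  CA  GLY A   2       2.600   3.600   0.000  1.00  0.00           C
ATOM      5  HN2 GLY A   3      -1.600   2.800   0.000  1.00  0.00           H
ATOM      6  C1  PET P 100       0.000   0.000   0.000  1.00  0.00           C
ATOM      7  O1  PET P 100       0.000   1.800   0.000  1.00  0.00           O
ATOM      8  O2  PET P 100       1.300  -0.600  -0.800  1.00  0.00           O
TER
END
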