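
Last position-specific scoring matrix computed, weighted, and scaled
            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V   A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 A     4  -1  -2  -2   0  -1  -1   0  -2  -1  -1  -1  -1  -2  -1   1   0  -3  -2   0    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.36 0.12
    2 K    -1   2   0  -1  -3   1   1  -2  -1  -3  -2   5  -1  -3  -1   0  -1  -3  -2  -2    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.41 0.12
    3 C     0  -3  -3  -3   2  -3  -4  -3  -3  -1  -1  -3  -1  -2  -3  -1  -1  -2  -2  -1    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.22 0.12

                      K         Lambda
Standard Ungapped    0.1347     0.3179
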