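>SYN0001 SOX-like_synthetic
A [ 88  4  2 90  4  2 86  6  4 30 ]
C [  4 88  4  2  6  2  4  6 84 30 ]
G [  4  4  4  4  2  6  6 82  6 20 ]
T [  4  4 90  4 88 90  4  6  6 20 ]
>SYN0002 null_synthetic
A [  4 86  4  4  2 88  4  4 84  4 ]
C [ 86  4  4  88 4  4  2 86  6  4 ]
G [  6  6 88  4  4  4  6  6  6 88 ]
T [  4  4  4  4 90  4 88  4  4  4 ]
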