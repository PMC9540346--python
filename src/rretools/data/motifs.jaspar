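>RT0001.1 SOXLIKE
A [  94   94    2   94   94    2    2    2   94 ]
C [   2    2   94    2    2    2    2    2    2 ]
G [   2    2    2    2    2    2   94   94    2 ]
T [   2    2    2    2    2   94    2    2    2 ]
>RT0002.1 SIXLIKE
A [   2    2   94    2    2    2    2    2    2 ]
C [   2   94    2    2    2    2    2    2   94 ]
G [   2    2    2   94   94    2    2    2    2 ]
T [  94    2    2    2    2   94   94   94    2 ]
>RT0003.1 CREBLIKE
A [   2    2   94    2    2    2    2   94    2 ]
C [   2    2    2   94    2    2   94    2    2 ]
G [   2   94    2    2   94    2    2    2    2 ]
T [  94    2    2    2    2   94    2    2   94 ]
>RT0004.1 ETSLIKE
A [   2    2    2    2   94   94    2    2    2 ]
C [  94   94    2    2    2    2    2    2    2 ]
G [   2    2   94   94    2    2    2    2   94 ]
T [   2    2    2    2    2    2   94   94    2 ]
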