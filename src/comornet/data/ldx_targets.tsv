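gene	effect
TAAR1	1
SLC18A2	-1
SLC6A3	-1
SLC6A2	-1
SLC6A4	-1
MAOA	-1
MAOB	-1
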