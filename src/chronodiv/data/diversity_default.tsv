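clade	described
Pycnogonida	1346
Xiphosura	4
Ricinulei	77
Opiliones	6571
Solifugae	1116
Acariformes	42233
Parasitiformes	12385
Pseudoscorpiones	3574
Scorpiones	2109
Uropygi	119
Amblypygi	172
Araneae	44863
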