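zone,superior_indices,inferior_indices
nasal_step,25;26;27,34;35;36
paracentral,19;21;22;23;24,28;30;31;32;33
arcuate_temporal,11;12;13;14,37;38;39;40
arcuate_nasal,15;16;17;18,41;42;43;44
peripheral,1;2;3;4;5;6;7;8;9;10,51;52;53;54;45;46;47;48;49;50
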