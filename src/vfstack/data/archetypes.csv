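name,indices
st_arcuate,5;6;7;8;11;12;13;14;15
in_arcuate,33;34;35;36;41;42;43;44
nasal_step,25;26;27
paracentral,21;22;23
diffuse,all
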