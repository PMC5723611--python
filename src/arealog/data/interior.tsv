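# Interior transects (1.2 ha), 12 Brazilian Atlantic forest fragments.
# Published rare-abundance classes only (f_1..f_7); the full survey had
# S = 371 species and M = 2174 individuals.
abundance	species
1	128
2	49
3	42
4	33
5	19
6	17
7	7
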