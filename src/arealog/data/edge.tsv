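# Edge transects (1.2 ha), 12 Brazilian Atlantic forest fragments.
# Published rare-abundance classes only (f_1..f_7); the full survey had
# S = 332 species and M = 1966 individuals.
abundance	species
1	115
2	49
3	38
4	28
5	14
6	11
7	13
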