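# Edge + interior transects combined (2.4 ha).
# Published rare-abundance classes only (f_1..f_7); the full survey had
# S = 443 species and M = 4140 individuals.
abundance	species
1	115
2	57
3	32
4	41
5	26
6	23
7	15
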