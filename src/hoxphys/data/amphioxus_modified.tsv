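# organism: amphioxus modified
# amphioxus cluster restricted to the paralog numbers present in mouse HoxD,
# with gene 14 retained as printed in the source data
gene_from	gene_to	distance_kbp
1	3	15
3	4	52
4	8	137
8	9	16
9	10	100
10	11	32
11	12	21
12	13	11
13	14	62
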