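# organism: amphioxus
# intergenic distances d(i,i+1) in Kbp, anterior (3') first
gene_from	gene_to	distance_kbp
1	2	10
2	3	5
3	4	52
4	5	63
5	6	11
6	7	42
7	8	21
8	9	16
9	10	100
10	11	32
11	12	21
12	13	11
13	14	62
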