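# organism: mouse HoxD
# intergenic distances d(i,i+1) in Kbp, anterior (3') first
gene_from	gene_to	distance_kbp
1	3	15
3	4	16
4	8	26
8	9	10
9	10	6
10	11	10
11	12	5
12	13	6
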