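label	value
Number of genic SNPs	238,484
Number of intergenic SNPs	452,178
Number of SNPs tiled with single probe	687,757
Number of SNPs tiled with two probes	2,905
Channel catfish-specific SNPs	581,002
Blue catfish-specific SNPs	44,694
Inter-species SNPs	19,124
Channel-blue both possessed	45,842
Strain-specific SNPs	48,434
Domesticate strain (Thompson)	12,672
Domesticate strain (Hatchery)	9,498
Domesticate strain (Marion)	10,309
Domesticate strain (USDA 103)	9,333
Wild population	6,622
Total number of SNPs on array	690,662
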