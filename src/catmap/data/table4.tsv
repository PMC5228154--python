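metric	backcross_hybrids	channel_catfish	total
Samples processed	84	396	480
Samples passed QC	81 (96.4%)	392 (98.9%)	473 (98.5%)
PolyHighResolution	292,185 (42.1%)	326,411 (47.1%)	401,815 (57.9%)
NoMinorHom	211,980 (30.6%)	141,410 (20.4%)	133,803 (19.3%)
Total Polymorphic SNPs	504,265 (72.7%)	467,821 (67.5%)	535,618 (77.2%)
MonoHighResolution	93,058 (13.4%)	111,047 (16.0%)	62,262 (8.9%)
Total converted SNPs	597,323 (86.1%)	578,868 (83.5%)	597,880 (86.1%)
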