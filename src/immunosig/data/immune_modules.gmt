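GC	germinal center markers	Gcsam	Nuggc	Rgs13	Klhl6	Aicda	Bcl6	Irf4
Tfh	T follicular helper markers	Bcl6	Pdcd1	Icos	Ascl2	Tnfsf4
PC_synthetic_placeholder	synthetic plasma-cell placeholder - replace with a curated PC signature	Sdc1	Prdm1	Xbp1	Jchain	Tnfrsf17
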