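# Default topology for a 348-residue bovine rhodopsin backbone.
# Implementer-provided approximation of the helix/loop architecture;
# override with your own TSV (segment<TAB>start<TAB>end, 1-based inclusive)
# if you work from a different boundary definition.
segment	start	end
NTERM	1	36
TM1	37	61
ICL1	62	72
TM2	73	97
ECL1	98	105
TM3	106	130
ICL2	131	150
TM4	151	173
ECL2	174	199
TM5	200	229
ICL3	230	246
TM6	247	276
ECL3	277	284
TM7	285	309
H8	310	321
CTERM	322	348
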