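code	tissue	total_reads	uniques
WS	whole seed 12-14 DAF	3000000	38749
SCR	seed coat immature (Richland)	2900000	32846
SCM	seed coat immature (Williams 55)	6100000	35413
SCW	seed coat immature (Williams)	2900000	27343
Cot	cotyledon immature	3000000	27288
GCot	germinating cotyledon	12500000	38961
ST	stem	4200000	37539
LE	leaf	6100000	6855
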