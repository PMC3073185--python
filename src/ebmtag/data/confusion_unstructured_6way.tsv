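# Published benchmark confusion matrix: six-way sentence classification over
# unstructured biomedical abstracts (rows = gold class, columns = predicted).
	Background	Intervention	Outcome	Population	Study Design	Other
Background	1505	15	272	70	2	24
Intervention	141	30	120	64	2	20
Outcome	496	13	1722	18	0	34
Population	161	24	73	158	1	26
Study Design	36	3	7	26	2	10
Other	170	11	245	15	0	89
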