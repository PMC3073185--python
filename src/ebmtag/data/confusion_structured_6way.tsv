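# Published benchmark confusion matrix: six-way sentence classification over
# structured biomedical abstracts (rows = gold class, columns = predicted).
	Background	Intervention	Outcome	Population	Study Design	Other
Background	561	4	43	8	2	51
Intervention	27	41	48	60	5	132
Outcome	6	1	2165	4	0	64
Population	24	17	33	198	10	87
Study Design	21	5	6	35	49	33
Other	63	24	155	30	8	754
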