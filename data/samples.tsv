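sample_id	condition	short_label
A1	A	A1
A2	A	A2
A3	A	A3
A4	A	A4
A5	A	A5
A6	A	A6
B1	B	B1
B2	B	B2
B3	B	B3
B4	B	B4
B5	B	B5
B6	B	B6
NT1	nontested	NT1
NT2	nontested	NT2
NT3	nontested	NT3
NT4	nontested	NT4
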