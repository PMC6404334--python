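term_id	affected	effect
GO:0000001	True	4.0
GO:0000002	False	0.0
GO:0000003	False	0.0
GO:0000004	False	0.0
GO:0000005	False	0.0
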