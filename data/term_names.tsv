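term_id	term_name
GO:0000001	affected set GO:0000001
GO:0000002	decoy set GO:0000002
GO:0000003	decoy set GO:0000003
GO:0000004	decoy set GO:0000004
GO:0000005	decoy set GO:0000005
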