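gene_id	term_id
G01	GO:0000001
G02	GO:0000001
G03	GO:0000001
G04	GO:0000001
G05	GO:0000001
G06	GO:0000001
G07	GO:0000001
G08	GO:0000001
G09	GO:0000001
G10	GO:0000001
G11	GO:0000002
G12	GO:0000002
G13	GO:0000002
G14	GO:0000002
G15	GO:0000002
G16	GO:0000002
G17	GO:0000002
G18	GO:0000002
G19	GO:0000002
G20	GO:0000002
G21	GO:0000003
G22	GO:0000003
G23	GO:0000003
G24	GO:0000003
G25	GO:0000003
G26	GO:0000003
G27	GO:0000003
G28	GO:0000003
G29	GO:0000003
G30	GO:0000003
G31	GO:0000004
G32	GO:0000004
G33	GO:0000004
G34	GO:0000004
G35	GO:0000004
G36	GO:0000004
G37	GO:0000004
G38	GO:0000004
G39	GO:0000004
G40	GO:0000004
G41	GO:0000005
G42	GO:0000005
G43	GO:0000005
G44	GO:0000005
G45	GO:0000005
G46	GO:0000005
G47	GO:0000005
G48	GO:0000005
G49	GO:0000005
G50	GO:0000005
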