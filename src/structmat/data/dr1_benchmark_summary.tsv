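pdb	md_contacts	md_contacts_sd	br_contacts	br_contacts_sd	md_hbonds	md_hbonds_sd	br_hbonds	br_hbonds_sd
1fyt	147.9	12.5	148.1	9.8	8.7	1.1	7.4	1.1
1klg	112.6	9.9	104.0	7.8	8.5	1.1	8.3	1.2
1sje	130.3	10.5	104.5	7.3	10.5	0.9	8.6	1.1
1sjh	115.1	10.6	107.8	9.9	8.4	1.1	9.9	1.0
1t5x	135.4	11.8	72.5	10.1	7.8	1.0	3.7	1.0
2fse	126.1	13.0	96.8	8.9	8.9	1.1	6.4	0.8
3pgd	129.9	13.5	133.3	9.4	9.2	1.1	8.7	0.7
4aen	114.6	11.3	99.0	7.6	8.2	1.2	7.4	1.1
4i5b	134.8	10.8	126.5	9.6	8.9	1.2	8.1	1.1
4ov5	161.1	13.8	133.9	11.0	10.2	1.2	8.5	0.7
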