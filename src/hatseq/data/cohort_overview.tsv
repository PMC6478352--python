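individual	cohort	matched_id	somatic_neuron	somatic_nonbrain	rate_neuron	rate_nonbrain	kr	knr	unk
4882	rett	4591	855	364	1.47	1.01	819	194	10
1815	rett	1571	589	306	1.30	0.68	806	189	11
4852	rett	1347	380	257	0.89	0.54	824	171	8
4516	rett	1846	759	411	1.82	0.69	814	195	7
1420	rett	1455	708	216	1.31	0.37	824	182	8
4591	control	4882	861	190	1.58	0.34	816	187	12
1571	control	1815	384	221	0.63	0.57	813	175	11
1347	control	4852	553	260	1.08	0.72	806	179	12
1846	control	4516	744	296	1.66	0.68	817	175	8
1455	control	1420	628	203	1.16	0.41	802	183	11
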