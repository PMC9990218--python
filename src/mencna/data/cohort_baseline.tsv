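patient_id	age_at_diagnosis	sex	ecog	year_diagnosed	initial_grade	final_grade	location	n_resections	radiation	status
A	22	F	0	2005	2	3	Convexity	3	Yes	Alive
B	71	M	1	2000	2	3	Convexity	3	Yes	Died 2003
C	59	F	0	1997	1	3	Parasagittal	6	Yes	Died 2008
D	62	M	2	2000	1	3	Sphenoid Wing	7	Yes	Died 2017
E	64	M	1	2003	1	2	Convexity	3	No	Alive
F	47	M	0	1997	1	2	Sphenoid Wing	3	Yes	Died 2007
G	65	F	1	1989	1	2	Falcine; CP angle	7	Yes	Died 2004
H	79	M	1	2000	1	2	Convexity	2	No	Died 2006
I	32	F	0	2006	1	2	Sphenoid Wing	3	Yes	Alive
J	33	M	0	1997	2	3	Sphenoid Wing; CP angle; Spinal Cord	10	Yes	Died 2009
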