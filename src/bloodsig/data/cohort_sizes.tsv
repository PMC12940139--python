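study_id	control_n	case_n	cohort_label
S01	46	58	liver cirrhosis
S02	102	79	smoking/HIV/SLE
S03	12	50	severe acute pancreatitis
S04	15	22	arteritis
S05	45	45	Parkinson's disease
S06	24	24	polycystic ovary syndrome
S07	77	64	type-1 diabetes
S08	117	0	healthy profiling
S09	13	13	sepsis
S10	26	0	healthy profiling
S11	35	213	febrile illness
S12	56	56	major depression
S13	30	60	Alzheimer's/MCI
S14	48	30	ME/CFS
S15	40	142	coronary heart disease/STEMI
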