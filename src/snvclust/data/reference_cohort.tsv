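id	group	population	sex	age	total_snvs
MA-Depresson-1	case	MA	Female	35	8348095
MA-Depresson-2	case	MA	Female	30	7921961
MA-Depresson-3	case	MA	Female	41	8037674
MA-Depresson-4	case	MA	Female	32	8021058
MA-Depresson-5	case	MA	Female	45	7839942
MA-Depresson-6	case	MA	Female	38	7834986
MA-Depresson-7	case	MA	Female	36	7935708
MA-Depresson-8	case	MA	Female	59	7694178
MA-Depresson-9	case	MA	Female	41	7778564
MA-Depresson-10	case	MA	Female	31	8073958
MA-Control-1	control	MA	Female	50	7879192
MA-Control-2	control	MA	Female	45	6974138
MA-Control-3	control	MA	Female	39	6911665
MA-Control-4	control	MA	Female	29	7197066
MA-Control-5	control	MA	Female	35	7487135
AU-Depresson-1	case	AU	Male	44	3883255
AU-Depresson-2	case	AU	Female	19	3938868
AU-Depresson-3	case	AU	Female	19	3925906
AU-Depresson-4	case	AU	Female	25	3933654
AU-Depresson-5	case	AU	Female	18	3905386
AU-Control-1	control	AU	Female	20	3898847
AU-Control-2	control	AU	Male	18	3920681
AU-Control-3	control	AU	Male	30	3861132
AU-Control-4	control	AU	Female	18	3922531
AU-Control-5	control	AU	Male	20	3820520
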