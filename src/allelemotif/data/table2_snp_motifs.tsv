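pwm	threshold_p0001	snp	ref_seq	alt_seq	delta	delta_rev	ref	ref_rev	alt	alt_rev	gene	distance
FOXA1_MOUSE.H11MO.0.A	8.11	rs30973633	TGTTTGCACA	TGTTTACACA	-2.60	-3.48	7.72	0.00	10.32	3.48	Defb30	10446
FOXA2_MOUSE.H11MO.0.A	8.13	rs48287999	CACTATTTACAAT	CACTATTTACCAT	1.39	0.00	8.16	0.00	6.76	0.00	Svs4	25871
FOXA2_MOUSE.H11MO.0.A	8.13	rs30973633	AGATGTTTGCACA	AGATGTTTACACA	-2.60	-2.22	6.25	0.00	8.86	2.22	Defb30	10446
FOXA3_MOUSE.H11MO.0.A	8.10	rs30973633	GATGTTTGCACAT	GATGTTTACACAT	-1.99	-1.47	6.73	0.00	8.73	1.47	Defb30	10446
ESR1_MOUSE.H11MO.1.A	7.80	rs32977910	CTGGGTCACA	CTGGGTCGCA	4.94	0.00	8.37	0.00	3.43	0.00	Svs3b	8536
AR_MOUSE.H11MO.1.A	8.02	rs28279710	CAGGAACAGGGA	CACGAACAGGGA	0.00	3.50	0	8.41	0	4.907	Svs4	0
AR_MOUSE.H11MO.1.A	8.02	rs46648903	CAGGAACAGGGA	CAGAAACAGGGA	0.00	3.59	0	8.41	0	4.825	Svs4	0
AR_MOUSE.H11MO.1.A	8.02	rs46677594	CAAGGACACGGA	CAAGGACATGGA	0.00	1.60	0	8.12	0	6.524	Svs4	26567
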