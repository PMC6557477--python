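group	gene	pattern	tissue	spermatogonia	spermatocytes	spermatids	trend_label	protein_function	hormone_annotation
SERPIN & proteases inhibitors	Serpina1b	generational	Spermatozoa	3.89	4.44	4.53	yes	Protease inhibitor	Glucocorticoid
SERPIN & proteases inhibitors	Serpina1e	generational	Spermatozoa	NA	NA	NA	NA	Protease inhibitor	Glucocorticoid
SERPIN & proteases inhibitors	Serpina3k	generational	Spermatozoa	3.28	3.43	3.55	yes	Protease inhibitor	Glucocorticoid
SERPIN & proteases inhibitors	Serpinc1	generational	Spermatozoa	4.17	4.19	4.43	yes	Protease inhibitor	Glucocorticoid
SERPIN & proteases inhibitors	Spink1	DEHP-susceptibility	Spermatozoa	3.37	3.43	3.64	yes	Protease inhibitor	Androgen
Seminal vesicle secretory proteins	Sva	DEHP-susceptibility	Seminal vesicle	3.39	3.54	3.73	yes	Capacitation suppression	Androgen
Seminal vesicle secretory proteins	Svs2	DEHP-susceptibility	Seminal vesicle	3.13	3.21	3.36	yes	Semen coagulation (Semenoglin I)	Androgen
Seminal vesicle secretory proteins	Svs3a	DEHP-susceptibility	Spermatozoa	4.12	4.57	4.53	no	Semen coagulation (semenogelin II)	Androgen
Seminal vesicle secretory proteins	Svs3b	DEHP-susceptibility	Spermatozoa	NA	NA	NA	NA	Semen coagulation (semenogelin II)	Androgen
Seminal vesicle secretory proteins	Svs4	DEHP-susceptibility	Spermatozoa	3.26	3.56	4.39	yes	Sperm capacitation inhibitor	Androgen
Seminal vesicle secretory proteins	Svs5	DEHP-susceptibility	Seminal vesicle	5.30	5.26	5.35	no	?	Androgen
Seminal vesicle secretory proteins	Svs6	DEHP-susceptibility	Seminal vesicle	3.16	3.23	3.30	yes	?	Androgen
Seminal vesicle secretory proteins	Pate4	DEHP-susceptibility	Spermatozoa	3.00	3.31	3.60	yes	Semen liquefaction	Androgen
Lipocalins	Lcn5	DEHP-resistance	Epididymis-specific	4.46	4.96	5.02	yes	Retinoic acid-binding	Androgen
Lipocalins	Lcn8	DEHP-resistance	Epididymis-specific	4.84	5.359	5.364	yes	Retinoic acid-binding	Androgen
Lipocalins	Lcn9	DEHP-resistance	Epididymis-specific	3.75	4.20	4.75	yes	Retinoic acid-binding	Androgen
Lipocalins	Mup3	generational	Urine	3.34	3.44	3.55	yes	Male-specific pheromone	Androgen
Defensins	Defb30	DEHP-resistance	Epididymis-specific	NA	NA	NA	NA	Innate immune protection	Androgen
Defensins	Spag11b	DEHP-resistance	Epididymis-specific	NA	NA	NA	NA	Innate immune protection	Androgen
Carboxylesterases	Ces1c	generational	Male reproductive tract	3.47	3.82	3.95	yes	Hydrolysis	Glucocorticoid
Carboxylesterases	Ces3a	generational	Male reproductive tract	NA	NA	NA	NA	Hydrolysis	Androgen
Clotting Factors	F2	generational	Serum & sperm	5.29	5.62	5.83	yes	Blood & seminal clotting	?
Clotting Factors	Fgb	generational	Serum & sperm	4.07	4.31	5.05	yes	Blood & seminal clotting	Glucocorticoid
Clotting Factors	Plg	generational	Serum & sperm	3.84	4.08	4.05	no	Blood & seminal clotting	Androgen regulator
Others	Gpx5	DEHP-resistance	Epididymis-specific	3.56	4.13	4.47	yes	oxydative stress protection	Androgen
Others	Pon1	generational	Serum & sperm	4.16	4.47	4.82	yes	removing thiolactone from proteins	Androgen
Others	Spint4	DEHP-resistance	Epididymis-specific	3.43	3.58	3.66	yes	control Ca2+ uptake by spermatozoa	Androgen
Others	9230104L09Rik	DEHP-resistance	Spermatozoa	5.30	6.03	6.16	yes	cysteine protease inhibitor	Androgen
Others	Wfdc21	generational	Epididymis-specific	4.72	4.85	5.02	yes	Innate immune functions	Estrogen
Cholesterol/steroid transport and metabolism	Apoa1	generational	High density lipoprotein & sperm	4.92	5.10	5.32	yes	Cholesterol transport	T3-Thyroid hormone
Cholesterol/steroid transport and metabolism	Apoa2	generational	High density lipoprotein	5.48	6.18	6.41	yes	Cholesterol transport	T3-Thyroid hormone
Cholesterol/steroid transport and metabolism	Apoc3	generational	Very-low-density lipoproteins	3.76	3.98	4.07	yes	Cholesterol transport	H-response enhancer
Cholesterol/steroid transport and metabolism	Apoh	generational	Liver	4.15	5.81	7.15	yes	Cholesterol transport & placental development and fetal growth	regulated by cis-acting elements
Cholesterol/steroid transport and metabolism	Apom	generational	High density lipoprotein	5.15	5.67	5.73	yes	Cholesterol transport	estrogen
Cholesterol/steroid transport and metabolism	Cml2	generational	Brain and testis	3.64	3.99	3.85	no	Lipids turnover	PPAR
Cholesterol/steroid transport and metabolism	Gc	generational	Serum & sperm	3.38	3.65	3.73	yes	Steroid transport (vitamin D)	-
Cholesterol/steroid transport and metabolism	Orm1	generational	Serum & sperm	3.05	3.18	3.30	yes	Steroid transport	Glucocorticoid
Cholesterol/steroid transport and metabolism	Cyp2d9	generational	Liver	3.66	4.03	4.28	yes	Steroid oxidation	Androgen
Cholesterol/steroid transport and metabolism	Cyp3a11	generational	Liver	3.22	3.29	3.23	no	Steroid metabolism	Testosterone hydroxylation
Cholesterol/steroid transport and metabolism	Fabp1	generational	Liver, serum	3.29	3.63	4.23	yes	Fatty acids transport	PPAR
Cholesterol/steroid transport and metabolism	Aldob	generational	Liver	4.67	5.07	5.77	yes	Glycolysis enzyme	Glucocorticoid
Cholesterol/steroid transport and metabolism	mir192	generational	Sperm and adipocytes	NA	NA	NA	NA	Lipid metabolism	Glucocorticoid
Cholesterol/steroid transport and metabolism	Saa2	DEHP-susceptibility	Serum & sperm	4.67	4.88	5.07	yes	Cholesterol transport & acute phase	Androgen
Glucocorticoid-regulated	Alb	generational	Liver	4.23	4.48	4.63	yes	Hormone carrier	Glucocorticoid
Glucocorticoid-regulated	Uox	generational	Liver	3.90	4.89	4.91	yes	Purine catabolism	Glucocorticoid
Glucocorticoid-regulated	Azgp1	generational	Adipocyte, prostate	4.97	5.41	5.87	yes	Lipid degradation	Glucocorticoid
Glucocorticoid-regulated	Cps1	generational	Testis	4.10	4.30	4.56	yes	Spermatogenesis	Glucocorticoid
PPARalpha-dependent	Slco1b2	generational	Liver	3.27	3.41	3.57	yes	Bile acids uptake	PPAR
PPARalpha-dependent	Sult2a8	generational	Liver	NA	NA	NA	NA	Conjugation of Dehydroepiandrosterone	PPAR
Hormones regulators	Akr1c6	generational	Liver	3.39	3.66	3.65	no	Reduction of androsterone to testosterone	regulator of sex hormones
Hormones regulators	Ahsg	generational	Serum, bones	5.39	5.14	5.75	no	Mineralization	regulator of lipids hormones
Hormones regulators	Rdh7	generational	Testis	3.58	3.73	3.79	yes	Androgen regulation	regulator of androgens activity
Probably hormono-dependent	Hpd	generational	Liver	4.02	3.87	3.91	no	Tyrosine catabolism	Hormone
Probably hormono-dependent	Bhmt	generational	Liver	4.53	5.48	4.44	no	methyltransferase in methionine synthesis	taurine-regulated
Probably hormono-dependent	Hamp	generational	Hepatocyte and blood	3.61	3.81	4.04	yes	master hormonal regulator of iron	peptide hormone
Probably hormono-dependent	C9	generational	Serum & sperm	4.21	4.70	5.27	yes	membrane attack complex, antisperm antibody	immuno-regulation
Probably hormono-dependent	Slc38a3	generational	Brain, Liver, Placenta	5.87	6.17	6.54	yes	transport of amino acids	Glucocorticoid
Not hormonally regulated	9530003J23Rik	DEHP-susceptibility	Spermatozoa	3.34	3.23	3.34	no	?	-
Not hormonally regulated	Haao	generational	Brain	4.98	5.59	5.74	yes	synthesis of Quinolinic acid	-
Not hormonally regulated	Ttc36	generational	Testis	4.67	5.40	5.77	yes	protein-protein interactions	-
Not hormonally regulated	Hpx	generational	Liver	4.27	4.46	4.41	no	serum iron-binding protein	-
Not hormonally regulated	Rprl3	DEHP-resistance	All cells	NA	NA	NA	NA	tRNA maturation	-
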