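# I-TASSER SPICKER Set-II benchmark: TM-score of the selected model (model1)
# per method on 56 protein decoy sets, plus decoy-set metadata.
target	length	size	best	kmeans_pp	sk_means	kmeans	spicker	random
1abv	103	526	0.507	0.3701	0.3834	0.4910	0.3813	0.479
1af7	72	527	0.623	0.5009	0.5009	0.4820	0.4874	0.322
1ah9	63	510	0.696	0.5040	0.4743	0.4740	0.4657	0.434
1aoy	65	529	0.711	0.6482	0.6695	0.6695	0.6695	0.622
1b4bA	71	460	0.473	0.3815	0.4279	0.4270	0.4501	0.379
1b72A	49	534	0.697	0.5397	0.3917	0.6410	0.4923	0.562
1bm8	99	329	0.388	0.4332	0.3787	0.3320	0.3550	0.255
1bq9A	53	573	0.465	0.3540	0.3459	0.3990	0.3873	0.411
1cewI	108	452	0.748	0.7294	0.7154	0.7290	0.7187	0.617
1cqkA	101	284	0.885	0.8439	0.8539	0.8539	0.8539	0.815
1csp	67	315	0.753	0.7158	0.7158	0.7158	0.7158	0.686
1cy5A	92	273	0.893	0.8685	0.8839	0.8680	0.8839	0.876
1dcjA	73	525	0.368	0.3299	0.3645	0.3170	0.3264	0.334
1di2A	69	374	0.843	0.7622	0.7663	0.7620	0.7663	0.374
1dtjA	74	285	0.814	0.7901	0.7581	0.7370	0.7901	0.705
1egxA	115	352	0.827	0.7673	0.7673	0.7673	0.7673	0.768
1fadA	92	514	0.652	0.5716	0.5755	0.5755	0.5755	0.553
1fo5A	85	340	0.568	0.5391	0.5391	0.5230	0.5296	0.469
1g1cA	98	307	0.787	0.7473	0.7732	0.7800	0.7732	0.621
1gjxA	77	525	0.515	0.2375	0.3807	0.3810	0.4298	0.191
1gnuA	117	553	0.647	0.5353	0.5353	0.5350	0.5456	0.509
1gpt	47	469	0.553	0.5130	0.5377	0.5060	0.4927	0.517
1gyvA	117	337	0.776	0.7406	0.7406	0.7540	0.7406	0.753
1hbkA	89	300	0.708	0.6633	0.6633	0.6633	0.6633	0.599
1itpA	68	526	0.511	0.3069	0.3152	0.3150	0.3096	0.335
1jnuA	104	269	0.768	0.7457	0.7237	0.6980	0.7237	0.711
1kjs	74	548	0.5	0.3728	0.3728	0.3580	0.3728	0.313
1kviA	68	550	0.79	0.7181	0.6774	0.7220	0.6774	0.642
1mkyA3	81	285	0.552	0.4155	0.4155	0.4155	0.4155	0.384
1mla_2	70	335	0.775	0.6742	0.6226	0.6226	0.6226	0.609
1mn8A	84	545	0.457	0.2517	0.3543	0.3540	0.3285	0.310
1n0uA4	69	301	0.588	0.4753	0.4746	0.4524	0.4524	0.333
1ne3A	56	566	0.453	0.2523	0.3943	0.3940	0.3724	0.344
1no5A	93	426	0.419	0.3710	0.4247	0.4240	0.4054	0.500
1npsA	88	469	0.800	0.7671	0.7671	0.2810	0.7671	0.283
1o2fB	77	510	0.528	0.3380	0.338	0.3370	0.2690	0.379
1of9A	77	507	0.585	0.5469	0.494	0.5460	0.4940	0.554
1ogwA	72	520	0.890	0.7853	0.7853	0.7850	0.8622	0.78
1orgA	118	442	0.816	0.7440	0.7339	0.7440	0.7440	0.693
1pgx	59	562	0.551	0.5824	0.3216	0.5160	0.4446	0.51
1r69	61	291	0.824	0.7007	0.7255	0.7255	0.7255	0.827
1sfp	111	308	0.758	0.7453	0.7453	0.7454	0.7454	0.749
1shfA	59	536	0.836	0.5649	0.5070	0.5640	0.5070	0.408
1sro	71	515	0.648	0.6513	0.6513	0.5820	0.6158	0.583
1ten	87	294	0.851	0.8215	0.8215	0.7860	0.8215	0.781
1tfi	47	339	0.592	0.5061	0.5576	0.5520	0.5576	0.550
1thx	108	302	0.865	0.8000	0.8000	0.8000	0.8000	0.819
1tif	59	542	0.340	0.3269	0.2667	0.2660	0.3199	0.232
1tig	88	565	0.585	0.5524	0.4596	0.4740	0.4176	0.517
1vcc	76	551	0.455	0.3973	0.4066	0.3970	0.4066	0.291
256bA	106	506	0.814	0.7657	0.7578	0.7650	0.7578	0.723
2a0b	118	282	0.838	0.8083	0.8083	0.8083	0.8083	0.768
2cr7A	60	540	0.666	0.3589	0.5059	0.5820	0.5136	0.365
2f3nA	65	485	0.758	0.6403	0.7322	0.6510	0.7132	0.626
2pcy	99	435	0.637	0.6040	0.5795	0.6460	0.6233	0.527
2reb_2	60	550	0.403	0.3902	0.378	0.3290	0.3174	0.416
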