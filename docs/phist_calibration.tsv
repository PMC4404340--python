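delta	lambda	expected	mean_phi_st	sd	reps
1	1.0	0.5000	0.5100	0.0488	50
1	2.0	0.3333	0.3373	0.0269	50
1	3.0	0.2500	0.2514	0.0213	50
1	4.0	0.2000	0.2059	0.0151	50
2	1.0	0.6667	0.6798	0.0386	50
2	2.0	0.5000	0.5006	0.0316	50
2	3.0	0.4000	0.4073	0.0268	50
2	4.0	0.3333	0.3354	0.0235	50
3	1.0	0.7500	0.7503	0.0302	50
3	2.0	0.6000	0.6093	0.0276	50
3	3.0	0.5000	0.5051	0.0260	50
3	4.0	0.4286	0.4311	0.0213	50
4	1.0	0.8000	0.8034	0.0325	50
4	2.0	0.6667	0.6650	0.0292	50
4	3.0	0.5714	0.5753	0.0276	50
4	4.0	0.5000	0.5077	0.0270	50
6	1.0	0.8571	0.8586	0.0247	50
6	2.0	0.7500	0.7528	0.0257	50
6	3.0	0.6667	0.6712	0.0236	50
6	4.0	0.6000	0.6077	0.0233	50
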