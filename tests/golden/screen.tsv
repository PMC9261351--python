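node_id	node_family	modality	direction	k	gene_set_size	hct_size	universe_size	odds_ratio	pvalue	qvalue	degenerate
node0030	fam0007	chipseq	down	10	15	40	391	23.0667	8.55654e-08	1.02678e-06	0
node0007	fam0001	transcriptomic	down	10	15	40	391	23.0667	8.55654e-08	1.19792e-06	0
node0028	fam0006	transcriptomic	down	10	15	40	391	23.0667	8.55654e-08	1.19792e-06	0
node0037	fam0009	chipseq	down	4	15	40	391	3.43434	0.0559327	0.335596	0
node0019	fam0004	transcriptomic	down	4	15	40	391	3.43434	0.0559327	0.522039	0
node0004	fam0000	transcriptomic	down	3	15	40	391	2.29054	0.190049	0.591262	0
node0008	fam0001	transcriptomic	down	3	15	40	391	2.29054	0.190049	0.591262	0
node0012	fam0002	transcriptomic	down	3	15	40	391	2.29054	0.190049	0.591262	0
node0013	fam0003	transcriptomic	down	3	15	40	391	2.29054	0.190049	0.591262	0
node0018	fam0004	transcriptomic	down	3	15	40	391	2.29054	0.190049	0.591262	0
node0022	fam0005	transcriptomic	down	3	15	40	391	2.29054	0.190049	0.591262	0
node0002	fam0000	transcriptomic	down	2	15	40	391	1.36842	0.466153	0.932307	0
node0003	fam0000	transcriptomic	down	2	15	40	391	1.36842	0.466153	0.932307	0
node0010	fam0002	transcriptomic	down	2	15	40	391	1.36842	0.466153	0.932307	0
node0021	fam0005	transcriptomic	down	2	15	40	391	1.36842	0.466153	0.932307	0
node0023	fam0005	transcriptomic	down	2	15	40	391	1.36842	0.466153	0.932307	0
node0005	fam0001	transcriptomic	down	1	15	40	391	0.617216	0.807998	0.983649	0
node0006	fam0001	transcriptomic	down	1	15	40	391	0.617216	0.807998	0.983649	0
node0014	fam0003	transcriptomic	down	1	15	40	391	0.617216	0.807998	0.983649	0
node0015	fam0003	transcriptomic	down	1	15	40	391	0.617216	0.807998	0.983649	0
node0016	fam0003	transcriptomic	down	1	15	40	391	0.617216	0.807998	0.983649	0
node0020	fam0004	transcriptomic	down	1	15	40	391	0.617216	0.807998	0.983649	0
node0025	fam0006	transcriptomic	down	1	15	40	391	0.617216	0.807998	0.983649	0
node0026	fam0006	transcriptomic	down	1	15	40	391	0.617216	0.807998	0.983649	0
node0027	fam0006	transcriptomic	down	1	15	40	391	0.617216	0.807998	0.983649	0
node0033	fam0008	chipseq	down	2	15	40	391	1.36842	0.466153	1	0
node0034	fam0008	chipseq	down	2	15	40	391	1.36842	0.466153	1	0
node0040	fam0009	chipseq	down	2	15	40	391	1.36842	0.466153	1	0
node0031	fam0007	chipseq	down	1	15	40	391	0.617216	0.807998	1	0
node0032	fam0007	chipseq	down	1	15	40	391	0.617216	0.807998	1	0
node0035	fam0008	chipseq	down	1	15	40	391	0.617216	0.807998	1	0
node0038	fam0009	chipseq	down	1	15	40	391	0.617216	0.807998	1	0
node0001	fam0000	transcriptomic	down	0	15	40	391	0.268021	1	1	1
node0009	fam0002	transcriptomic	down	0	15	40	391	0.268021	1	1	1
node0011	fam0002	transcriptomic	down	0	15	40	391	0.268021	1	1	1
node0017	fam0004	transcriptomic	down	0	15	40	391	0.268021	1	1	1
node0024	fam0005	transcriptomic	down	0	15	40	391	0.268021	1	1	1
node0029	fam0007	chipseq	down	0	15	40	391	0.268021	1	1	1
node0036	fam0008	chipseq	down	0	15	40	391	0.268021	1	1	1
node0039	fam0009	chipseq	down	0	15	40	391	0.268021	1	1	1
node0029	fam0007	chipseq	up	10	14	40	391	28.9167	3.07374e-08	1.84424e-07	0
node0032	fam0007	chipseq	up	10	14	40	391	28.9167	3.07374e-08	1.84424e-07	0
node0002	fam0000	transcriptomic	up	10	14	40	391	28.9167	3.07374e-08	8.60647e-07	0
node0036	fam0008	chipseq	up	4	14	40	391	3.78889	0.0442567	0.177027	0
node0034	fam0008	chipseq	up	3	14	40	391	2.50614	0.163225	0.489676	0
node0007	fam0001	transcriptomic	up	4	14	40	391	3.78889	0.0442567	0.619594	0
node0006	fam0001	transcriptomic	up	3	14	40	391	2.50614	0.163225	0.761718	0
node0014	fam0003	transcriptomic	up	3	14	40	391	2.50614	0.163225	0.761718	0
node0020	fam0004	transcriptomic	up	3	14	40	391	2.50614	0.163225	0.761718	0
node0024	fam0005	transcriptomic	up	3	14	40	391	2.50614	0.163225	0.761718	0
node0001	fam0000	transcriptomic	up	2	14	40	391	1.48684	0.429339	1	0
node0017	fam0004	transcriptomic	up	2	14	40	391	1.48684	0.429339	1	0
node0022	fam0005	transcriptomic	up	2	14	40	391	1.48684	0.429339	1	0
node0023	fam0005	transcriptomic	up	2	14	40	391	1.48684	0.429339	1	0
node0027	fam0006	transcriptomic	up	2	14	40	391	1.48684	0.429339	1	0
node0003	fam0000	transcriptomic	up	1	14	40	391	0.666667	0.785208	1	0
node0005	fam0001	transcriptomic	up	1	14	40	391	0.666667	0.785208	1	0
node0008	fam0001	transcriptomic	up	1	14	40	391	0.666667	0.785208	1	0
node0010	fam0002	transcriptomic	up	1	14	40	391	0.666667	0.785208	1	0
node0012	fam0002	transcriptomic	up	1	14	40	391	0.666667	0.785208	1	0
node0021	fam0005	transcriptomic	up	1	14	40	391	0.666667	0.785208	1	0
node0025	fam0006	transcriptomic	up	1	14	40	391	0.666667	0.785208	1	0
node0031	fam0007	chipseq	up	1	14	40	391	0.666667	0.785208	1	0
node0035	fam0008	chipseq	up	1	14	40	391	0.666667	0.785208	1	0
node0037	fam0009	chipseq	up	1	14	40	391	0.666667	0.785208	1	0
node0038	fam0009	chipseq	up	1	14	40	391	0.666667	0.785208	1	0
node0040	fam0009	chipseq	up	1	14	40	391	0.666667	0.785208	1	0
node0004	fam0000	transcriptomic	up	0	14	40	391	0.287356	1	1	1
node0009	fam0002	transcriptomic	up	0	14	40	391	0.287356	1	1	1
node0011	fam0002	transcriptomic	up	0	14	40	391	0.287356	1	1	1
node0013	fam0003	transcriptomic	up	0	14	40	391	0.287356	1	1	1
node0015	fam0003	transcriptomic	up	0	14	40	391	0.287356	1	1	1
node0016	fam0003	transcriptomic	up	0	14	40	391	0.287356	1	1	1
node0018	fam0004	transcriptomic	up	0	14	40	391	0.287356	1	1	1
node0019	fam0004	transcriptomic	up	0	14	40	391	0.287356	1	1	1
node0026	fam0006	transcriptomic	up	0	14	40	391	0.287356	1	1	1
node0028	fam0006	transcriptomic	up	0	14	40	391	0.287356	1	1	1
node0030	fam0007	chipseq	up	0	14	40	391	0.287356	1	1	1
node0033	fam0008	chipseq	up	0	14	40	391	0.287356	1	1	1
node0039	fam0009	chipseq	up	0	14	40	391	0.287356	1	1	1
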