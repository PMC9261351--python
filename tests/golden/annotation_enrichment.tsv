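term_id	label	direction	k	n_hits	n_annotated	odds_ratio	pvalue	degenerate
term0001	synthetic term 1	up	3	3	8	41.3636	0.00566802	True
term0002	synthetic term 2	up	3	3	8	41.3636	0.00566802	True
term0003	synthetic term 3	up	0	3	8	0.495798	1	True
term0004	synthetic term 4	up	0	3	8	0.495798	1	True
term0005	synthetic term 5	up	1	3	8	2.14286	0.497976	False
term0006	synthetic term 6	up	1	3	8	2.14286	0.497976	False
term0007	synthetic term 7	up	1	3	8	2.14286	0.497976	False
term0008	synthetic term 8	up	0	3	8	0.495798	1	True
term0009	synthetic term 9	up	1	3	8	2.14286	0.497976	False
term0010	synthetic term 10	up	2	3	8	10.3333	0.0963563	False
term0011	synthetic term 11	up	0	3	8	0.495798	1	True
term0012	synthetic term 12	up	0	3	8	0.495798	1	True
term0013	synthetic term 13	up	0	3	8	0.495798	1	True
term0014	synthetic term 14	up	0	3	8	0.495798	1	True
term0015	synthetic term 15	up	0	3	8	0.495798	1	True
term0016	synthetic term 16	up	0	3	8	0.495798	1	True
term0017	synthetic term 17	up	0	3	8	0.495798	1	True
term0018	synthetic term 18	up	0	3	8	0.495798	1	True
term0019	synthetic term 19	up	1	3	8	2.14286	0.497976	False
term0020	synthetic term 20	up	1	3	8	2.14286	0.497976	False
term0001	synthetic term 1	down	3	3	8	41.3636	0.00566802	True
term0002	synthetic term 2	down	3	3	8	41.3636	0.00566802	True
term0003	synthetic term 3	down	2	3	8	10.3333	0.0963563	False
term0004	synthetic term 4	down	1	3	8	2.14286	0.497976	False
term0005	synthetic term 5	down	1	3	8	2.14286	0.497976	False
term0006	synthetic term 6	down	0	3	8	0.495798	1	True
term0007	synthetic term 7	down	0	3	8	0.495798	1	True
term0008	synthetic term 8	down	0	3	8	0.495798	1	True
term0009	synthetic term 9	down	0	3	8	0.495798	1	True
term0010	synthetic term 10	down	1	3	8	2.14286	0.497976	False
term0011	synthetic term 11	down	2	3	8	10.3333	0.0963563	False
term0012	synthetic term 12	down	1	3	8	2.14286	0.497976	False
term0013	synthetic term 13	down	0	3	8	0.495798	1	True
term0014	synthetic term 14	down	1	3	8	2.14286	0.497976	False
term0015	synthetic term 15	down	0	3	8	0.495798	1	True
term0016	synthetic term 16	down	0	3	8	0.495798	1	True
term0017	synthetic term 17	down	0	3	8	0.495798	1	True
term0018	synthetic term 18	down	1	3	8	2.14286	0.497976	False
term0019	synthetic term 19	down	0	3	8	0.495798	1	True
term0020	synthetic term 20	down	1	3	8	2.14286	0.497976	False
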