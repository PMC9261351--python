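ko_up	FC>1.5 p<0.05	g000023	g000037	g000041	g000060	g000086	g000088	g000094	g000108	g000140	g000150	g000314	g000332	g000335	g000398
ko_down	FC<1/1.5 p<0.05	g000030	g000035	g000052	g000149	g000153	g000169	g000171	g000184	g000186	g000196	g000211	g000260	g000331	g000346	g000397
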