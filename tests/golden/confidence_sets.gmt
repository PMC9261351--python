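induced_confidence_transcripts	CQV<0.05 gmfc_log2>1.0	g000023	g000037	g000041	g000086	g000088	g000108	g000140	g000150	g000332
repressed_confidence_transcripts	CQV<0.05 gmfc_log2<-1.0	g000052	g000149	g000153	g000171	g000184	g000186	g000260	g000346	g000397
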