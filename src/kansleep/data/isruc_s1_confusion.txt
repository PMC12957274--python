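# Published benchmark confusion matrix: 5-stage sleep scoring on the
# ISRUC-S1 subset (50 subjects, 25-fold subject-independent CV, pooled).
# rows = true stage, columns = predicted; order W N1 N2 N3 REM
W	9261	582	175	16	63
N1	866	2826	1480	29	354
N2	250	871	11059	839	231
N3	16	12	1396	7249	2
REM	146	374	437	3	4819
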