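# Published benchmark confusion matrix: 5-stage sleep scoring on the
# Sleep-EDF-153 dataset (10-fold session-independent CV, pooled) after
# sleep-state-focus balancing (edge wake trimmed to 30 min per side).
# rows = true stage, columns = predicted; order W N1 N2 N3 REM
W	58875	2941	379	37	324
N1	3873	10589	5032	74	1693
N2	588	4442	59170	1661	2184
N3	26	37	4927	7891	18
REM	476	1059	1907	10	21830
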