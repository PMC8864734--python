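pair	gene_class	cis_only	trans_only	both_codir	both_antidir	neither
MED	outlier	20	74	6	14	70
MED	nonoutlier	199	2203	99	324	1357
ETH	outlier	12	136	10	14	59
ETH	nonoutlier	297	2224	137	379	1532
SAF	outlier	22	47	0	15	83
SAF	nonoutlier	250	691	40	738	2274
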