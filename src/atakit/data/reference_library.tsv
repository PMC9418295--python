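id	fingerprint	role	activity_class	annotation
TA-3N5M	MWYRGGN	reference	beta_alanine_pyruvate	beta-alanine:pyruvate transaminase, tetramer (Bacillus anthracis, Q81SL2; KT861634)
TA-2OAT	YSFSEKT	reference	acetylornithine	acetylornithine transaminase (Homo sapiens, P04181)
TA-3HMU	FWYMARV	reference	high_amine	highly active amine transaminase (Silicibacter pomeroyi, Q5LMU1)
TA-3FCR	SYYFTRM	reference	low_amine	low-activity amine transaminase (Silicibacter sp. TM1040, Q1GD43)
TA-4E3Q	FWYNARL	reference	high_amine	highly active amine transaminase (Vibrio fluvialis, F2XBU9)
TA-1	LWYRGGT	investigated	uncharacterized	taurine:pyruvate transaminase (Bilophila wadsworthia, Q9APM5; MT828894)
TA-2	LWYRGGT	investigated	uncharacterized	putative transaminase (Ruegeria pomeroyi, Q5LVM7; MT828895)
TA-3	WMYRSAM	investigated	uncharacterized	putative transaminase (halophilic archaeon, G2MNN2; MT828896)
TA-4	GMYRTYR	investigated	uncharacterized	putative transaminase (uncultured bacterium, C7FP94; MT828897)
TA-5	FAYRTYM	investigated	uncharacterized	putative transaminase (Halomonas elongata, E1V8W4; MT828898)
TA-6	YSFMAEE	investigated	uncharacterized	putative transaminase (Clostridium sp., F0YVE9; MT828899)
TA-7	FFYATRD	investigated	uncharacterized	putative transaminase (Streptomyces sp., D9VFY2; MT828900)
TA-8	FGYFPRA	investigated	uncharacterized	putative transaminase (Verminephrobacter sp., A1WHB0; MT828901)
TA-9	RFYYTRL	investigated	uncharacterized	putative transaminase (Burkholderia cepacia, B4EHM2; MT828902)
TA-10	MWYFARV	investigated	uncharacterized	putative transaminase (Burkholderia multivorans, B9AZ94; MT828903)
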