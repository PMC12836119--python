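species	strain	locality	beta0	se0	beta1	se1
C. elegans	fog-2	NA	1.517	0.156	-0.219	0.313
C. remanei	EM464	New York	3.330	0.272	-1.816	0.376
C. remanei	PB219	Ohio	2.730	0.220	-1.974	0.356
C. remanei	QG548	Okinawa	3.935	0.334	-2.123	0.427
C. remanei	QG549	Okinawa	4.038	0.372	-1.320	0.464
C. kamaaina	QG122	Kaua'i	3.633	0.299	-2.048	0.398
C. kamaaina	QG123	Kaua'i	3.134	0.252	-1.931	0.368
C. panamensis	QG702	Panama	4.403	0.380	-2.798	0.478
C. panamensis	QG703	Panama	4.391	0.383	-2.675	0.478
C. becei	QG704	Panama	3.513	0.307	-0.899	0.402
C. becei	QG711	Panama	3.671	0.325	-0.985	0.419
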