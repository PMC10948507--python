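# Published 15-genotype verification panel for the seven-trait tolerance model:
# three genotypes per grade, with the full-assay D value and the model's printed Y.
grade,genotype_id,SNC,RNIL,RWC,RGR,RKC,Sen,RNC,D,Y
HST,M135,68.5235,0.6722,10.6811,1.3153,21.8653,4.1111,35.7473,0.6528,0.6504
HST,M399,77.2951,0.5873,9.6401,0.4770,17.0181,4.7778,42.9012,0.6321,0.5707
HST,M275,71.7442,0.5595,7.4736,1.0119,15.0141,4.3333,42.2869,0.6307,0.6034
ST,M29,76.0937,0.7806,7.5559,1.0206,24.2159,3.6667,57.0360,0.5981,0.6041
ST,M372,109.2919,0.6699,19.1205,0.2283,24.4107,4.7778,44.9874,0.5663,0.5647
ST,M42,101.2471,0.6257,10.9623,0.7333,17.8049,5.2222,54.8780,0.5376,0.5447
MST,M235,86.6145,0.4393,6.5162,0.4582,20.1583,5.0000,53.5684,0.5143,0.5000
MST,M333,143.8789,0.5833,9.5685,0.4326,25.8235,5.6667,42.7207,0.4513,0.4496
MST,M166,128.6327,0.2922,15.0708,0.4771,29.3749,6.5556,43.3426,0.4477,0.4386
SS,M160,120.8193,0.4180,7.0272,0.4324,22.1833,7.2222,30.6579,0.4331,0.4312
SS,M397,135.6414,0.0000,6.0231,0.8124,23.4249,6.3333,42.5636,0.3975,0.3786
SS,M318,155.5016,0.4563,10.2639,0.4746,26.3178,7.8889,41.0854,0.3845,0.3816
HSS,M268,148.0509,0.0741,9.1441,0.4711,28.2644,7.0000,55.8626,0.3481,0.3352
HSS,M336,161.1194,0.2323,8.8758,0.1580,22.0328,7.6667,50.8735,0.3180,0.3273
HSS,M411,177.6243,0.2667,8.4277,0.0350,29.2614,7.0000,33.9501,0.3172,0.3167
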