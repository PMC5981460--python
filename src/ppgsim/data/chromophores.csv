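# Synthetic compilation of chromophore absorption spectra for ppgsim.
# Whole-blood HbO2/Hb at 150 g hemoglobin per liter, from standard
# molar-extinction compilations; water from Pope/Fry and Hale/Querry;
# lipid from van Veen-style measurements. Anchor values interpolated
# (monotone cubic) onto a 5 nm grid. Units: nm, cm^-1.
wavelength_nm,mua_hbo2_cm1,mua_hb_cm1,mua_water_cm1,mua_fat_cm1
450,336.37,451.12,0.00011,0.055
455,281.98,383.23,0.00011164,0.047424
460,238.18,321.29,0.00011613,0.040463
465,204.22,263.11,0.00012279,0.034521
470,177.83,214.19,0.00013097,0.03
475,157.37,176.75,0.00014,0.026495
480,142.59,149.94,0.00015228,0.023353
485,133.89,133.83,0.00016976,0.020603
490,126.82,123.16,0.0001911,0.018275
495,118.46,115.43,0.00021496,0.016397
500,112.09,111.71,0.00024,0.015
505,108.78,115.43,0.00026861,0.013912
510,107.28,123.16,0.00030241,0.012938
515,114.32,133.95,0.0003389,0.012066
520,130.42,149.94,0.00037559,0.011287
525,167.12,178.09,0.00041,0.010591
530,213.96,209.03,0.00044071,0.0099672
535,254.77,231.42,0.0004694,0.0094064
540,285.07,249.49,0.00049824,0.0088984
545,297.41,262.39,0.00052939,0.0084329
550,230.34,283.46,0.000565,0.008
555,192.77,294.52,0.00060239,0.0075893
560,181.51,286.01,0.00064111,0.0071984
565,196.52,267.74,0.00068662,0.0068291
570,238.27,254.36,0.00074443,0.0064832
575,297.41,240.97,0.00082,0.0061625
580,268.3,198.24,0.00099458,0.0058688
585,166,176.71,0.0012962,0.0056039
590,77.11,149.94,0.0016505,0.0053696
595,34.807,109.77,0.0019832,0.0051677
600,17.136,78.593,0.00222,0.005
605,10.485,66.936,0.0023664,0.0048505
610,8.0644,56.226,0.0024856,0.004704
615,6.3569,48.237,0.0025896,0.0045635
620,5.0443,41.768,0.0026904,0.004432
625,4.0249,36.276,0.0028,0.0043125
630,3.2665,32.129,0.0029149,0.004208
635,2.7361,29.755,0.003027,0.0041215
640,2.3668,27.572,0.0031417,0.004056
645,2.1389,24.136,0.0032643,0.0040145
650,1.9706,20.884,0.0034,0.004
655,1.8257,18.846,0.0035481,0.0040072
660,1.7136,17.28,0.0037075,0.004028
665,1.6356,16.061,0.0038828,0.0040608
670,1.5743,14.994,0.0040788,0.004104
675,1.5119,13.914,0.0043,0.0041563
680,1.4779,12.889,0.004537,0.004216
685,1.4848,11.915,0.0047964,0.0042817
690,1.4994,11.031,0.0051074,0.004352
695,1.521,10.267,0.0054989,0.0044253
700,1.5529,9.6066,0.006,0.0045
705,1.6008,9.0502,0.0069283,0.004596
710,1.66,8.5678,0.0084424,0.004728
715,1.7216,8.1784,0.010332,0.004887
720,1.7885,7.7645,0.012388,0.005064
725,1.8561,6.9697,0.0144,0.00525
730,1.9385,6.4258,0.016674,0.005436
735,2.0685,6.6043,0.019365,0.005613
740,2.2276,6.9613,0.02204,0.005772
745,2.3848,7.463,0.024263,0.005904
750,2.5703,8.0323,0.0256,0.006
755,2.8541,8.6105,0.026287,0.006068
760,3.1379,8.9426,0.0266,0.006124
765,3.3213,8.2737,0.026309,0.006171
770,3.4807,7.229,0.025639,0.006212
775,3.644,6.5205,0.0249,0.00625
780,3.8019,5.8903,0.024023,0.006288
785,3.9553,5.3159,0.022903,0.006329
790,4.1018,4.8194,0.021791,0.006376
795,4.2383,4.3798,0.02094,0.006432
800,4.3696,4.075,0.0206,0.0065
805,4.4974,3.9447,0.021075,0.0065795
810,4.6266,3.8555,0.022333,0.0066693
815,4.7638,3.765,0.024124,0.0067714
820,4.905,3.7109,0.026197,0.0068878
825,5.0496,3.6993,0.0283,0.0070206
830,5.1942,3.6948,0.030748,0.0071717
835,5.3404,3.7002,0.033802,0.0073432
840,5.4727,3.7056,0.037131,0.0075371
845,5.5741,3.7029,0.040407,0.0077553
850,5.6654,3.7002,0.0433,0.008
855,5.7581,3.7088,0.045752,0.0083061
860,5.8475,3.727,0.048004,0.0087239
865,5.9355,3.7547,0.050169,0.0092776
870,6.0227,3.7952,0.052363,0.0099919
875,6.1052,3.8418,0.0547,0.010891
880,6.1795,3.8876,0.056919,0.012
885,6.2454,3.9412,0.058948,0.014134
890,6.3061,4.003,0.061188,0.017968
895,6.3623,4.0539,0.064039,0.023318
900,6.4151,4.075,0.0679,0.03
905,6.4724,4.0576,0.074982,0.043423
910,6.5318,4.0146,0.086789,0.063101
915,6.5784,3.9604,0.10267,0.08
920,6.5972,3.909,0.12196,0.093333
925,6.5885,3.8627,0.144,0.105
930,6.5661,3.814,0.1809,0.11
935,6.5351,3.7634,0.23661,0.099153
940,6.5008,3.7109,0.29828,0.077196
945,6.4571,3.6539,0.35303,0.06
950,6.3989,3.5928,0.388,0.051408
955,6.3327,3.5333,0.40557,0.044721
960,6.2652,3.4807,0.4186,0.04
965,6.1953,3.4327,0.43,0.036659
970,6.1197,3.3867,0.44288,0.033975
975,6.042,3.3475,0.45,0.031803
980,5.9653,3.32,0.44337,0.03
985,5.8903,3.3003,0.43,0.028398
990,5.8154,3.2832,0.41325,0.026979
995,5.7404,3.2711,0.39059,0.02582
1000,5.6654,3.2665,0.363,0.025
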