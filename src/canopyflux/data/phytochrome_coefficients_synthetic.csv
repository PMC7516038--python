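# SYNTHETIC phytochrome photoconversion coefficient table.
# Gaussian parameterization of P_r (peak 665 nm) and P_fr (peak 730 nm)
# calibrated to canonical photoequilibrium behaviour (monochromatic red ~0.9,
# blue ~0.5); NOT measured cross-sections. Substitute a measured table for real work.
wavelength_nm,sigma_r,sigma_fr
380,0.008913,0.008913
382,0.009895,0.009895
384,0.010949,0.010949
386,0.012076,0.012076
388,0.013275,0.013275
390,0.014546,0.014546
392,0.015887,0.015887
394,0.017295,0.017295
396,0.018766,0.018766
398,0.020295,0.020295
400,0.021878,0.021878
402,0.023508,0.023508
404,0.025176,0.025176
406,0.026875,0.026875
408,0.028595,0.028595
410,0.030327,0.030327
412,0.032058,0.032058
414,0.033777,0.033777
416,0.035472,0.035472
418,0.037132,0.037132
420,0.038742,0.038742
422,0.040290,0.040290
424,0.041764,0.041764
426,0.043150,0.043150
428,0.044437,0.044437
430,0.045613,0.045613
432,0.046667,0.046667
434,0.047591,0.047591
436,0.048374,0.048374
438,0.049010,0.049010
440,0.049492,0.049492
442,0.049817,0.049817
444,0.049980,0.049980
446,0.049980,0.049980
448,0.049817,0.049817
450,0.049492,0.049492
452,0.049010,0.049010
454,0.048374,0.048374
456,0.047591,0.047591
458,0.046667,0.046667
460,0.045613,0.045613
462,0.044437,0.044437
464,0.043150,0.043150
466,0.041764,0.041764
468,0.040290,0.040290
470,0.038742,0.038742
472,0.037132,0.037132
474,0.035472,0.035473
476,0.033777,0.033777
478,0.032058,0.032058
480,0.030327,0.030327
482,0.028595,0.028596
484,0.026875,0.026875
486,0.025176,0.025176
488,0.023508,0.023508
490,0.021878,0.021879
492,0.020295,0.020296
494,0.018766,0.018766
496,0.017295,0.017295
498,0.015887,0.015888
500,0.014546,0.014548
502,0.013275,0.013277
504,0.012076,0.012079
506,0.010949,0.010952
508,0.009895,0.009899
510,0.008913,0.008919
512,0.008003,0.008010
514,0.007162,0.007171
516,0.006388,0.006401
518,0.005680,0.005695
520,0.005034,0.005053
522,0.004446,0.004471
524,0.003915,0.003946
526,0.003435,0.003475
528,0.003005,0.003054
530,0.002620,0.002681
532,0.002277,0.002353
534,0.001973,0.002067
536,0.001704,0.001820
538,0.001468,0.001610
540,0.001260,0.001435
542,0.001080,0.001293
544,0.000924,0.001182
546,0.000789,0.001102
548,0.000676,0.001051
550,0.000580,0.001031
552,0.000503,0.001040
554,0.000443,0.001079
556,0.000400,0.001150
558,0.000374,0.001254
560,0.000369,0.001393
562,0.000386,0.001570
564,0.000429,0.001787
566,0.000505,0.002049
568,0.000621,0.002360
570,0.000787,0.002724
572,0.001017,0.003146
574,0.001327,0.003631
576,0.001739,0.004186
578,0.002280,0.004817
580,0.002981,0.005531
582,0.003884,0.006333
584,0.005036,0.007233
586,0.006493,0.008235
588,0.008324,0.009349
590,0.010607,0.010580
592,0.013433,0.011935
594,0.016906,0.013421
596,0.021144,0.015044
598,0.026277,0.016809
600,0.032450,0.018721
602,0.039818,0.020782
604,0.048550,0.022995
606,0.058819,0.025362
608,0.070808,0.027881
610,0.084698,0.030551
612,0.100668,0.033367
614,0.118888,0.036325
616,0.139510,0.039417
618,0.162667,0.042634
620,0.188460,0.045963
622,0.216951,0.049393
624,0.248160,0.052908
626,0.282049,0.056491
628,0.318524,0.060123
630,0.357424,0.063786
632,0.398521,0.067459
634,0.441513,0.071120
636,0.486028,0.074748
638,0.531624,0.078321
640,0.577795,0.081818
642,0.623979,0.085221
644,0.669565,0.088512
646,0.713909,0.091675
648,0.756348,0.094700
650,0.796213,0.097579
652,0.832852,0.100310
654,0.865640,0.102894
656,0.894005,0.105340
658,0.917438,0.107663
660,0.935514,0.109886
662,0.947899,0.112038
664,0.954367,0.114155
666,0.954801,0.116282
668,0.949201,0.118469
670,0.937682,0.120774
672,0.920470,0.123261
674,0.897898,0.125995
676,0.870391,0.129047
678,0.838455,0.132488
680,0.802663,0.136387
682,0.763637,0.140810
684,0.722028,0.145816
686,0.678503,0.151454
688,0.633725,0.157764
690,0.588335,0.164769
692,0.542941,0.172475
694,0.498103,0.180869
696,0.454327,0.189915
698,0.412050,0.199556
700,0.371642,0.209711
702,0.333403,0.220276
704,0.297559,0.231123
706,0.264268,0.242104
708,0.233622,0.253053
710,0.205654,0.263789
712,0.180344,0.274121
714,0.157628,0.283851
716,0.137401,0.292781
718,0.119530,0.300719
720,0.103860,0.307482
722,0.090220,0.312905
724,0.078431,0.316842
726,0.068308,0.319177
728,0.059671,0.319821
730,0.052345,0.318718
732,0.046162,0.315847
734,0.040966,0.311224
736,0.036615,0.304899
738,0.032977,0.296954
740,0.029938,0.287505
742,0.027395,0.276693
744,0.025259,0.264683
746,0.023453,0.251657
748,0.021913,0.237811
750,0.020584,0.223346
752,0.019421,0.208467
754,0.018387,0.193374
756,0.017452,0.178260
758,0.016593,0.163302
760,0.015792,0.148664
762,0.015034,0.134491
764,0.014310,0.120906
766,0.013611,0.108009
768,0.012932,0.095881
770,0.012271,0.084578
772,0.011625,0.074136
774,0.010992,0.064573
776,0.010374,0.055888
778,0.009770,0.048065
780,0.009181,0.041076
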