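wavelength_nm,eps_oxy,eps_deoxy
350,25788,30600
355,24627.3,30295.8
360,22947,29402.2
365,21081.1,27979.2
370,19864.8,26137.8
375,21365.4,24091.4
380,30094.8,22316.8
385,54043.2,21952.7
390,103655,25548.1
395,186517,38024.1
400,298275,67083.3
405,415929,121605
410,502385,206830
415,524332,317441
420,472409,433145
425,367298,522453
430,246423,555801
435,142693,521005
440,71371.1,430185
445,30907.3,312847
450,11677.4,200434
455,3953.64,113210
460,1315.87,56484.8
465,546.036,25033.1
470,352.809,10019.4
475,310.565,3810.45
480,302.306,1579
485,301.258,891.431
490,304.64,744.958
495,324.811,822.05
500,415.972,1102.76
505,756.965,1720.79
510,1813.98,2929.57
515,4516.66,5087.33
520,10172.3,8603.57
525,19730.1,13815.8
530,32447,20802.1
535,45016.2,29188.6
540,52627.5,38052.4
545,51998,46020.8
550,44175.8,51594.2
555,34664,53600
560,30472.6,51594.2
565,35515.6,46020.8
570,46832.4,38052.4
575,55419,29188.6
580,53232.1,20802.1
585,40324.5,13815.7
590,23943.5,8603.35
595,11187.6,5086.87
600,4205.94,2928.66
605,1391.64,5587.68
610,538.017,4839.65
615,341.09,4424.24
620,306.625,4178.79
625,302.563,4013.49
630,303.095,3883.93
635,304.548,3770.28
640,306.666,3664.48
645,309.623,3563.47
650,313.677,3466.17
655,319.137,3372.17
660,326.362,3281.28
665,335.752,3193.38
670,347.736,3108.36
675,362.747,3026.12
680,381.201,2946.58
685,403.453,2869.65
690,429.759,2795.25
695,460.231,2723.28
700,494.791,2653.67
705,533.135,2586.34
710,574.7,2521.22
715,618.658,2458.24
720,663.918,2397.32
725,709.164,2338.39
730,752.904,2281.4
735,793.547,2226.28
740,829.498,2172.96
745,859.261,2121.4
750,881.54,2071.52
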