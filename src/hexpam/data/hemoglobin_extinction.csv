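wavelength_nm,eps_hbo2,eps_hbr
500,20932,20862
510,20035,26100
520,24202,30500
530,39956,39036
532,44480,40584
540,53236,46592
545,52076,50092
550,43016,52428
555,36024,53412
558,33896,53300
560,32620,53412
565,35464,51000
570,44496,45072
576,50104,38440
580,47000,37020
590,14677,26630
600,3200,14677
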