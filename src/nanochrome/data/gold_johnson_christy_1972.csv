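wavelength_nm,n,k
354.2406,1.5,1.866
367.9056,1.48,1.895
381.4898,1.46,1.933
397.3852,1.47,1.952
413.2806,1.46,1.958
430.5007,1.45,1.948
450.8516,1.38,1.914
471.4228,1.31,1.849
495.9368,1.04,1.833
520.9420,0.62,2.081
548.6026,0.43,2.455
582.0854,0.29,2.863
616.8368,0.21,3.272
659.4904,0.14,3.697
704.4556,0.13,4.103
756.0012,0.14,4.542
821.0874,0.16,5.083
891.9726,0.17,5.663
984.0015,0.22,6.35
1087.5806,0.27,7.15
1215.5313,0.35,8.145
1393.0808,0.43,9.519
1610.1843,0.56,11.21
1937.2530,0.92,13.78
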