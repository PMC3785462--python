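alpha,beta,n_sc_star
0.1,0.5,2.768200407
0.1,0.55,3.109183202
0.1,0.6,3.450227093
0.1,0.65,3.822698241
0.1,0.7,4.285423826
0.1,0.75,4.850530548
0.1,0.8,5.442679884
0.1,0.85,6.206433531
0.1,0.9,7.039376279
0.1,0.95,8.536024747
0.05,0.5,3.619964706
0.05,0.55,3.985916764
0.05,0.6,4.446467
0.05,0.65,4.944713054
0.05,0.7,5.425609643
0.05,0.75,6.016993961
0.05,0.8,6.624145719
0.05,0.85,7.268768491
0.05,0.9,8.290250065
0.05,0.95,9.972004675
0.01,0.5,5.745417492
0.01,0.55,6.223832437
0.01,0.6,6.66315867
0.01,0.65,7.105052765
0.01,0.7,7.612019233
0.01,0.75,8.225862856
0.01,0.8,8.946473683
0.01,0.85,9.786015665
0.01,0.9,11.02474402
0.01,0.95,12.70334342
0.005,0.5,6.552256615
0.005,0.55,6.969988878
0.005,0.6,7.412996353
0.005,0.65,7.920214514
0.005,0.7,8.513412899
0.005,0.75,9.135178569
0.005,0.8,9.877022486
0.005,0.85,10.9104924
0.005,0.9,12.07853007
0.005,0.95,14.00366916
0.001,0.5,8.209831599
0.001,0.55,8.736024799
0.001,0.6,9.282695314
0.001,0.65,9.899595423
0.001,0.7,10.60514766
0.001,0.75,11.336645
0.001,0.8,12.08570835
0.001,0.85,13.05590969
0.001,0.9,14.46709712
0.001,0.95,16.25926555
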