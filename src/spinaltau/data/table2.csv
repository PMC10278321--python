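needle,replicate,height_cm,time_s
22G Pajunk Sprotte,M1,1,7.477
22G Pajunk Sprotte,M1,2,15.262
22G Pajunk Sprotte,M1,3,23.532
22G Pajunk Sprotte,M1,4,32.746
22G Pajunk Sprotte,M1,5,42.85
22G Pajunk Sprotte,M1,6,54.429
22G Pajunk Sprotte,M1,7,67.493
22G Pajunk Sprotte,M1,8,82.794
22G Pajunk Sprotte,M1,9,99.915
22G Pajunk Sprotte,M1,10,121.72
22G Pajunk Sprotte,M1,11,149.557
22G Pajunk Sprotte,M1,12,188.186
22G Pajunk Sprotte,M1,13,254.348
22G Pajunk Sprotte,M2,1,7.297
22G Pajunk Sprotte,M2,2,15.119
22G Pajunk Sprotte,M2,3,23.608
22G Pajunk Sprotte,M2,4,32.903
22G Pajunk Sprotte,M2,5,43.497
22G Pajunk Sprotte,M2,6,54.859
22G Pajunk Sprotte,M2,7,67.913
22G Pajunk Sprotte,M2,8,83.742
22G Pajunk Sprotte,M2,9,101.705
22G Pajunk Sprotte,M2,10,123.534
22G Pajunk Sprotte,M2,11,152.16
22G Pajunk Sprotte,M2,12,191.823
22G Pajunk Sprotte,M2,13,262.977
22G Pajunk Sprotte,M3,1,7.664
22G Pajunk Sprotte,M3,2,15.226
22G Pajunk Sprotte,M3,3,23.465
22G Pajunk Sprotte,M3,4,32.833
22G Pajunk Sprotte,M3,5,43.014
22G Pajunk Sprotte,M3,6,54.507
22G Pajunk Sprotte,M3,7,67.464
22G Pajunk Sprotte,M3,8,82.705
22G Pajunk Sprotte,M3,9,100.722
22G Pajunk Sprotte,M3,10,120.855
22G Pajunk Sprotte,M3,11,149.105
22G Pajunk Sprotte,M3,12,187.137
22G Pajunk Sprotte,M3,13,251.124
22G M. Schilling,M1,1,11.223
22G M. Schilling,M1,2,23.453
22G M. Schilling,M1,3,36.503
22G M. Schilling,M1,4,50.713
22G M. Schilling,M1,5,66.54
22G M. Schilling,M1,6,84.133
22G M. Schilling,M1,7,103.875
22G M. Schilling,M1,8,126.741
22G M. Schilling,M1,9,153.524
22G M. Schilling,M1,10,182.494
22G M. Schilling,M1,11,225.71
22G M. Schilling,M1,12,280.662
22G M. Schilling,M1,13,365.752
22G M. Schilling,M2,1,11.484
22G M. Schilling,M2,2,23.559
22G M. Schilling,M2,3,36.263
22G M. Schilling,M2,4,50.764
22G M. Schilling,M2,5,66.495
22G M. Schilling,M2,6,84.582
22G M. Schilling,M2,7,104.351
22G M. Schilling,M2,8,127.224
22G M. Schilling,M2,9,154.463
22G M. Schilling,M2,10,186.791
22G M. Schilling,M2,11,227.57
22G M. Schilling,M2,12,282.595
22G M. Schilling,M2,13,368.164
22G M. Schilling,M3,1,11.529
22G M. Schilling,M3,2,23.418
22G M. Schilling,M3,3,36.098
22G M. Schilling,M3,4,50.099
22G M. Schilling,M3,5,66.246
22G M. Schilling,M3,6,83.735
22G M. Schilling,M3,7,103.339
22G M. Schilling,M3,8,125.766
22G M. Schilling,M3,9,152.368
22G M. Schilling,M3,10,183.667
22G M. Schilling,M3,11,223.957
22G M. Schilling,M3,12,277.612
22G M. Schilling,M3,13,360.552
22G Braun Spinocan,M1,1,13.843
22G Braun Spinocan,M1,2,29.669
22G Braun Spinocan,M1,3,46.654
22G Braun Spinocan,M1,4,65.669
22G Braun Spinocan,M1,5,86.268
22G Braun Spinocan,M1,6,109.424
22G Braun Spinocan,M1,7,135.146
22G Braun Spinocan,M1,8,164.203
22G Braun Spinocan,M1,9,199.339
22G Braun Spinocan,M1,10,242.336
22G Braun Spinocan,M1,11,296.737
22G Braun Spinocan,M1,12,369.026
22G Braun Spinocan,M1,13,486.537
22G Braun Spinocan,M2,1,13.414
22G Braun Spinocan,M2,2,29.356
22G Braun Spinocan,M2,3,46.242
22G Braun Spinocan,M2,4,64.521
22G Braun Spinocan,M2,5,84.756
22G Braun Spinocan,M2,6,107.42
22G Braun Spinocan,M2,7,132.06
22G Braun Spinocan,M2,8,161.072
22G Braun Spinocan,M2,9,195.063
22G Braun Spinocan,M2,10,234.635
22G Braun Spinocan,M2,11,286.846
22G Braun Spinocan,M2,12,354.984
22G Braun Spinocan,M2,13,456.29
22G Braun Spinocan,M3,1,14.705
22G Braun Spinocan,M3,2,30.154
22G Braun Spinocan,M3,3,47.304
22G Braun Spinocan,M3,4,64.483
22G Braun Spinocan,M3,5,84.804
22G Braun Spinocan,M3,6,107.443
22G Braun Spinocan,M3,7,132.327
22G Braun Spinocan,M3,8,161.821
22G Braun Spinocan,M3,9,196.323
22G Braun Spinocan,M3,10,236.528
22G Braun Spinocan,M3,11,288.835
22G Braun Spinocan,M3,12,359.79
22G Braun Spinocan,M3,13,469.991
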