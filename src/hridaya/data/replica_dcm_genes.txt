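HD00012
HD00027
HD00032
HD00064
HD00065
HD00077
HD00095
HD00098
HD00100
HD00111
HD00114
HD00126
HD00128
HD00134
HD00164
HD00172
HD00176
HD00187
HD00211
HD00218
HD00223
HD00231
HD00266
HD00270
HD00278
HD00294
HD00321
HD00322
HD00325
HD00335
HD00356
HD00376
HD00384
HD00400
HD00443
HD00473
HD00498
HD00500
HD00501
HD00503
HD00525
HD00532
HD00535
HD00549
HD00570
HD00616
HD00646
HD00648
HD00684
HD00686
HD00704
HD00771
HD00798
HD00841
HD00850
HD00853
HD00891
HD00895
HD00904
HD00959
HD00963
HD00967
HD01006
HD01040
HD01045
HD01056
HD01074
HD01085
HD01088
HD01124
HD01128
HD01144
HD01176
HD01181
HD01191
HD01235
HD01252
HD01259
HD01267
HD01304
HD01312
HD01366
HD01372
HD01404
HD01409
HD01411
HD01421
HD01435
HD01502
HD01507
HD01519
HD01522
HD01523
HD01542
HD01545
HD01554
HD01562
HD01602
HD01647
HD01654
HD01658
HD01693
HD01700
HD01701
HD01706
HD01707
HD01710
HD01723
HD01745
HD01757
HD01759
HD01763
HD01764
HD01790
HD01826
HD01833
HD01850
HD01855
HD01867
HD01893
HD01909
HD01933
HD01934
HD01938
HD01945
HD01966
HD01979
HD02031
HD02049
HD02105
HD02110
HD02139
HD02152
HD02174
HD02277
HD02279
HD02302
HD02320
HD02347
HD02348
HD02382
HD02383
HD02410
HD02455
HD02462
HD02486
HD02527
HD02531
HD02533
HD02535
HD02539
HD02567
HD02584
HD02601
HD02613
HD02618
HD02619
HD02622
HD02626
HD02648
HD02675
HD02676
HD02711
HD02717
HD02721
HD02722
HD02731
HD02743
HD02757
HD02775
HD02787
HD02794
HD02797
HD02810
HD02848
HD02869
HD02870
HD02879
HD02887
HD02897
HD02906
HD02912
HD02935
HD02937
HD02954
HD02987
HD02998
HD03010
HD03014
HD03017
HD03031
HD03034
HD03036
HD03064
HD03065
HD03086
HD03093
HD03098
HD03119
HD03130
HD03135
HD03137
HD03144
HD03175
HD03181
HD03204
HD03207
HD03212
HD03220
HD03228
HD03243
HD03267
HD03287
HD03289
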