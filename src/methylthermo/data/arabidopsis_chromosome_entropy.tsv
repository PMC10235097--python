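# Published per-chromosome Gibbs entropy estimates (J K^-1 mol^-1, molar units,
# J-divergence based) for Arabidopsis thaliana wild-type controls, msh1
# memory/non-memory progeny (generations 1 and 3) and the met1 mutant.
# group: experimental group label; control_group: matched wild-type control.
sample	group	control_group	chromosome	entropy
WT3-1	WT3		1	-12.095
WT3-1	WT3		2	-13.092
WT3-1	WT3		3	-12.854
WT3-1	WT3		4	-12.875
WT3-1	WT3		5	-12.398
WT3-2	WT3		1	-12.239
WT3-2	WT3		2	-13.202
WT3-2	WT3		3	-12.827
WT3-2	WT3		4	-12.955
WT3-2	WT3		5	-12.447
WT3-3	WT3		1	-12.582
WT3-3	WT3		2	-13.611
WT3-3	WT3		3	-13.312
WT3-3	WT3		4	-13.403
WT3-3	WT3		5	-12.872
WT3-4	WT3		1	-12.190
WT3-4	WT3		2	-13.289
WT3-4	WT3		3	-12.884
WT3-4	WT3		4	-13.008
WT3-4	WT3		5	-12.534
WT3-5	WT3		1	-13.010
WT3-5	WT3		2	-14.074
WT3-5	WT3		3	-13.806
WT3-5	WT3		4	-13.831
WT3-5	WT3		5	-13.333
nm1_1	nm1	WT3	1	-10.517
nm1_1	nm1	WT3	2	-11.671
nm1_1	nm1	WT3	3	-11.430
nm1_1	nm1	WT3	4	-11.447
nm1_1	nm1	WT3	5	-10.970
nm1_2	nm1	WT3	1	-10.344
nm1_2	nm1	WT3	2	-11.461
nm1_2	nm1	WT3	3	-11.193
nm1_2	nm1	WT3	4	-11.205
nm1_2	nm1	WT3	5	-10.758
nm1_3	nm1	WT3	1	-13.424
nm1_3	nm1	WT3	2	-14.234
nm1_3	nm1	WT3	3	-14.126
nm1_3	nm1	WT3	4	-14.175
nm1_3	nm1	WT3	5	-13.761
nm1_4	nm1	WT3	1	-10.332
nm1_4	nm1	WT3	2	-11.428
nm1_4	nm1	WT3	3	-11.160
nm1_4	nm1	WT3	4	-11.192
nm1_4	nm1	WT3	5	-10.740
nm1_5	nm1	WT3	1	-14.458
nm1_5	nm1	WT3	2	-14.972
nm1_5	nm1	WT3	3	-15.002
nm1_5	nm1	WT3	4	-14.804
nm1_5	nm1	WT3	5	-14.614
mm1_1	mm1	WT3	1	-12.452
mm1_1	mm1	WT3	2	-13.385
mm1_1	mm1	WT3	3	-13.153
mm1_1	mm1	WT3	4	-13.134
mm1_1	mm1	WT3	5	-12.807
mm1_2	mm1	WT3	1	-13.170
mm1_2	mm1	WT3	2	-14.111
mm1_2	mm1	WT3	3	-13.934
mm1_2	mm1	WT3	4	-13.978
mm1_2	mm1	WT3	5	-13.579
mm1_3	mm1	WT3	1	-10.485
mm1_3	mm1	WT3	2	-11.578
mm1_3	mm1	WT3	3	-11.391
mm1_3	mm1	WT3	4	-11.369
mm1_3	mm1	WT3	5	-10.947
mm1_4	mm1	WT3	1	-10.087
mm1_4	mm1	WT3	2	-11.177
mm1_4	mm1	WT3	3	-10.972
mm1_4	mm1	WT3	4	-10.982
mm1_4	mm1	WT3	5	-10.485
mm1_5	mm1	WT3	1	-9.969
mm1_5	mm1	WT3	2	-11.104
mm1_5	mm1	WT3	3	-10.818
mm1_5	mm1	WT3	4	-10.852
mm1_5	mm1	WT3	5	-10.298
mm3_1	mm3	WT3	1	-9.504
mm3_1	mm3	WT3	2	-10.593
mm3_1	mm3	WT3	3	-10.366
mm3_1	mm3	WT3	4	-10.370
mm3_1	mm3	WT3	5	-9.850
mm3_2	mm3	WT3	1	-9.617
mm3_2	mm3	WT3	2	-10.691
mm3_2	mm3	WT3	3	-10.537
mm3_2	mm3	WT3	4	-10.528
mm3_2	mm3	WT3	5	-10.014
mm3_3	mm3	WT3	1	-9.392
mm3_3	mm3	WT3	2	-10.475
mm3_3	mm3	WT3	3	-10.269
mm3_3	mm3	WT3	4	-10.264
mm3_3	mm3	WT3	5	-9.839
mm3_4	mm3	WT3	1	-10.336
mm3_4	mm3	WT3	2	-11.407
mm3_4	mm3	WT3	3	-11.292
mm3_4	mm3	WT3	4	-11.310
mm3_4	mm3	WT3	5	-10.825
mm3_5	mm3	WT3	1	-9.688
mm3_5	mm3	WT3	2	-10.736
mm3_5	mm3	WT3	3	-10.531
mm3_5	mm3	WT3	4	-10.526
mm3_5	mm3	WT3	5	-10.083
WT_met1_1	WT_met1		1	-3.751
WT_met1_1	WT_met1		2	-4.061
WT_met1_1	WT_met1		3	-3.958
WT_met1_1	WT_met1		4	-3.738
WT_met1_1	WT_met1		5	-3.700
WT_met1_2	WT_met1		1	-5.876
WT_met1_2	WT_met1		2	-6.242
WT_met1_2	WT_met1		3	-6.164
WT_met1_2	WT_met1		4	-5.959
WT_met1_2	WT_met1		5	-5.811
WT_met1_3	WT_met1		1	-5.869
WT_met1_3	WT_met1		2	-6.216
WT_met1_3	WT_met1		3	-6.070
WT_met1_3	WT_met1		4	-5.896
WT_met1_3	WT_met1		5	-5.727
WT_met1_4	WT_met1		1	-5.994
WT_met1_4	WT_met1		2	-6.347
WT_met1_4	WT_met1		3	-6.178
WT_met1_4	WT_met1		4	-5.995
WT_met1_4	WT_met1		5	-5.889
met1_1	met1	WT_met1	1	2.183
met1_1	met1	WT_met1	2	2.129
met1_1	met1	WT_met1	3	2.065
met1_1	met1	WT_met1	4	1.980
met1_1	met1	WT_met1	5	2.085
met1_2	met1	WT_met1	1	1.199
met1_2	met1	WT_met1	2	1.126
met1_2	met1	WT_met1	3	1.072
met1_2	met1	WT_met1	4	1.004
met1_2	met1	WT_met1	5	1.108
met1_3	met1	WT_met1	1	2.032
met1_3	met1	WT_met1	2	1.993
met1_3	met1	WT_met1	3	1.923
met1_3	met1	WT_met1	4	1.848
met1_3	met1	WT_met1	5	1.946
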