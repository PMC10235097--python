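# Published per-chromosome Gibbs entropy estimates (J K^-1 mol^-1, molar units,
# J-divergence versus a common blood B-cell reference) for human healthy tissues,
# matched cancers/metastases, and naive embryonic stem cell replicates (hesc).
tissue	chromosome	entropy
Brain	1	-16.34
Brain	2	-16.49
Brain	3	-16.65
Brain	4	-16.79
Brain	5	-16.48
Brain	6	-16.53
Brain	7	-16.51
Brain	8	-16.38
Brain	9	-16.13
Brain	10	-16.26
Brain	11	-16.02
Brain	12	-16.41
Brain	13	-16.56
Brain	14	-16.12
Brain	15	-16.39
Brain	16	-15.87
Brain	17	-15.96
Brain	18	-16.42
Brain	19	-16.10
Brain	20	-15.72
Brain	21	-15.99
Brain	22	-15.64
Brain	X	-17.69
Glioma	1	-1.54
Glioma	2	-1.52
Glioma	3	-2.29
Glioma	4	-2.66
Glioma	5	-1.26
Glioma	6	-2.15
Glioma	7	3.60
Glioma	8	-0.82
Glioma	9	-2.01
Glioma	10	0.47
Glioma	11	0.05
Glioma	12	-1.38
Glioma	13	-1.84
Glioma	14	-1.45
Glioma	15	-1.92
Glioma	16	-0.65
Glioma	17	-2.33
Glioma	18	-1.69
Glioma	19	3.93
Glioma	20	0.10
Glioma	21	-0.23
Glioma	22	-0.97
Glioma	X	0.94
Breast	1	-14.13
Breast	2	-14.64
Breast	3	-14.77
Breast	4	-15.05
Breast	5	-14.62
Breast	6	-14.62
Breast	7	-14.56
Breast	8	-14.37
Breast	9	-14.08
Breast	10	-14.20
Breast	11	-13.88
Breast	12	-14.33
Breast	13	-15.05
Breast	14	-14.24
Breast	15	-14.49
Breast	16	-13.42
Breast	17	-13.61
Breast	18	-14.58
Breast	19	-13.10
Breast	20	-13.47
Breast	21	-13.47
Breast	22	-12.91
Breast	X	-15.32
Breast Cancer	1	-1.04
Breast Cancer	2	-0.09
Breast Cancer	3	0.50
Breast Cancer	4	1.94
Breast Cancer	5	2.89
Breast Cancer	6	-0.77
Breast Cancer	7	2.39
Breast Cancer	8	1.63
Breast Cancer	9	-1.27
Breast Cancer	10	2.39
Breast Cancer	11	2.19
Breast Cancer	12	1.25
Breast Cancer	13	3.12
Breast Cancer	14	0.29
Breast Cancer	15	0.05
Breast Cancer	16	2.12
Breast Cancer	17	-4.08
Breast Cancer	18	2.20
Breast Cancer	19	-3.64
Breast Cancer	20	0.28
Breast Cancer	21	1.06
Breast Cancer	22	-1.47
Breast Cancer	X	5.68
Breast Metastasis	1	2.61
Breast Metastasis	2	4.75
Breast Metastasis	3	4.65
Breast Metastasis	4	6.79
Breast Metastasis	5	6.07
Breast Metastasis	6	3.56
Breast Metastasis	7	4.73
Breast Metastasis	8	6.68
Breast Metastasis	9	3.24
Breast Metastasis	10	5.65
Breast Metastasis	11	5.22
Breast Metastasis	12	3.42
Breast Metastasis	13	6.29
Breast Metastasis	14	4.67
Breast Metastasis	15	3.00
Breast Metastasis	16	3.55
Breast Metastasis	17	2.14
Breast Metastasis	18	6.90
Breast Metastasis	19	2.61
Breast Metastasis	20	4.86
Breast Metastasis	21	5.77
Breast Metastasis	22	2.88
Breast Metastasis	X	7.50
Colon	1	-14.50
Colon	2	-14.68
Colon	3	-14.77
Colon	4	-14.48
Colon	5	-14.46
Colon	6	-14.87
Colon	7	-14.78
Colon	8	-14.52
Colon	9	-14.38
Colon	10	-14.71
Colon	11	-14.18
Colon	12	-14.74
Colon	13	-14.56
Colon	14	-14.58
Colon	15	-15.03
Colon	16	-14.50
Colon	17	-14.42
Colon	18	-14.60
Colon	19	-14.11
Colon	20	-13.94
Colon	21	-14.32
Colon	22	-13.97
Colon	X	-15.25
Colon Cancer	1	-9.93
Colon Cancer	2	-10.46
Colon Cancer	3	-10.87
Colon Cancer	4	-9.57
Colon Cancer	5	-9.47
Colon Cancer	6	-10.65
Colon Cancer	7	-10.09
Colon Cancer	8	-9.27
Colon Cancer	9	-10.33
Colon Cancer	10	-10.39
Colon Cancer	11	-9.70
Colon Cancer	12	-10.52
Colon Cancer	13	-8.89
Colon Cancer	14	-10.10
Colon Cancer	15	-10.52
Colon Cancer	16	-9.61
Colon Cancer	17	-10.71
Colon Cancer	18	-8.68
Colon Cancer	19	-9.87
Colon Cancer	20	-8.38
Colon Cancer	21	-8.80
Colon Cancer	22	-10.04
Colon Cancer	X	-8.93
Colon Metastasis	1	-6.65
Colon Metastasis	2	-6.16
Colon Metastasis	3	-6.40
Colon Metastasis	4	-5.53
Colon Metastasis	5	-4.80
Colon Metastasis	6	-6.22
Colon Metastasis	7	-5.18
Colon Metastasis	8	-4.23
Colon Metastasis	9	-6.44
Colon Metastasis	10	-5.93
Colon Metastasis	11	-5.21
Colon Metastasis	12	-6.52
Colon Metastasis	13	-4.50
Colon Metastasis	14	-6.11
Colon Metastasis	15	-6.53
Colon Metastasis	16	-5.74
Colon Metastasis	17	-7.78
Colon Metastasis	18	-5.41
Colon Metastasis	19	-6.15
Colon Metastasis	20	-4.43
Colon Metastasis	21	-4.44
Colon Metastasis	22	-7.69
Colon Metastasis	X	-2.41
Lung	1	-16.51
Lung	2	-16.78
Lung	3	-16.86
Lung	4	-17.19
Lung	5	-16.90
Lung	6	-16.82
Lung	7	-16.73
Lung	8	-16.80
Lung	9	-16.55
Lung	10	-16.62
Lung	11	-16.55
Lung	12	-16.65
Lung	13	-17.00
Lung	14	-16.66
Lung	15	-16.74
Lung	16	-16.10
Lung	17	-15.97
Lung	18	-16.90
Lung	19	-16.10
Lung	20	-16.07
Lung	21	-16.24
Lung	22	-15.62
Lung	X	-16.60
Lung Cancer	1	-8.38
Lung Cancer	2	-9.62
Lung Cancer	3	-9.90
Lung Cancer	4	-7.90
Lung Cancer	5	-6.79
Lung Cancer	6	-6.84
Lung Cancer	7	-8.03
Lung Cancer	8	-6.22
Lung Cancer	9	-8.52
Lung Cancer	10	-6.39
Lung Cancer	11	-6.31
Lung Cancer	12	-6.99
Lung Cancer	13	-9.00
Lung Cancer	14	-8.80
Lung Cancer	15	-9.00
Lung Cancer	16	-7.55
Lung Cancer	17	-7.81
Lung Cancer	18	-9.59
Lung Cancer	19	-3.28
Lung Cancer	20	-5.39
Lung Cancer	21	-6.21
Lung Cancer	22	-9.85
Lung Cancer	X	-3.90
Adenocarcinoma	1	0.19
Adenocarcinoma	2	0.56
Adenocarcinoma	3	1.43
Adenocarcinoma	4	4.47
Adenocarcinoma	5	3.70
Adenocarcinoma	6	0.12
Adenocarcinoma	7	1.30
Adenocarcinoma	8	3.61
Adenocarcinoma	9	0.30
Adenocarcinoma	10	1.37
Adenocarcinoma	11	0.86
Adenocarcinoma	12	0.58
Adenocarcinoma	13	4.92
Adenocarcinoma	14	0.45
Adenocarcinoma	15	5.27
Adenocarcinoma	16	0.95
Adenocarcinoma	17	-1.69
Adenocarcinoma	18	4.41
Adenocarcinoma	19	-0.77
Adenocarcinoma	20	0.62
Adenocarcinoma	21	1.08
Adenocarcinoma	22	-1.24
Adenocarcinoma	X	4.54
Squamous Cancer	1	2.92
Squamous Cancer	2	5.30
Squamous Cancer	3	4.77
Squamous Cancer	4	6.07
Squamous Cancer	5	6.25
Squamous Cancer	6	5.67
Squamous Cancer	7	5.10
Squamous Cancer	8	7.12
Squamous Cancer	9	3.86
Squamous Cancer	10	5.66
Squamous Cancer	11	5.90
Squamous Cancer	12	3.71
Squamous Cancer	13	4.68
Squamous Cancer	14	4.37
Squamous Cancer	15	4.18
Squamous Cancer	16	3.26
Squamous Cancer	17	-0.42
Squamous Cancer	18	6.82
Squamous Cancer	19	0.76
Squamous Cancer	20	5.80
Squamous Cancer	21	3.65
Squamous Cancer	22	1.06
Squamous Cancer	X	7.84
hesc_1	1	1.99
hesc_1	2	1.96
hesc_1	3	1.95
hesc_1	4	1.80
hesc_1	5	1.86
hesc_1	6	1.95
hesc_1	7	1.98
hesc_1	8	1.90
hesc_1	9	1.99
hesc_1	10	1.96
hesc_1	11	1.91
hesc_1	12	1.97
hesc_1	13	1.88
hesc_1	14	1.95
hesc_1	15	1.98
hesc_1	16	2.10
hesc_1	17	2.08
hesc_1	18	1.90
hesc_1	19	2.09
hesc_1	20	1.97
hesc_1	21	1.99
hesc_1	22	2.15
hesc_1	X	0.52
hesc_2	1	1.66
hesc_2	2	1.62
hesc_2	3	1.61
hesc_2	4	1.41
hesc_2	5	1.49
hesc_2	6	1.61
hesc_2	7	1.65
hesc_2	8	1.53
hesc_2	9	1.64
hesc_2	10	1.60
hesc_2	11	1.54
hesc_2	12	1.64
hesc_2	13	1.51
hesc_2	14	1.61
hesc_2	15	1.65
hesc_2	16	1.76
hesc_2	17	1.79
hesc_2	18	1.53
hesc_2	19	1.80
hesc_2	20	1.59
hesc_2	21	1.62
hesc_2	22	1.84
hesc_2	X	0.05
hesc_3	1	1.73
hesc_3	2	1.70
hesc_3	3	1.69
hesc_3	4	1.53
hesc_3	5	1.60
hesc_3	6	1.69
hesc_3	7	1.72
hesc_3	8	1.64
hesc_3	9	1.73
hesc_3	10	1.70
hesc_3	11	1.65
hesc_3	12	1.72
hesc_3	13	1.61
hesc_3	14	1.69
hesc_3	15	1.72
hesc_3	16	1.84
hesc_3	17	1.83
hesc_3	18	1.63
hesc_3	19	1.85
hesc_3	20	1.70
hesc_3	21	1.73
hesc_3	22	1.90
hesc_3	X	0.21
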