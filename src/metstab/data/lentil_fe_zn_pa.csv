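genotype,environment,trait,value
DPL 62,Delhi,Fe,82.14
DPL 62,Kanpur,Fe,80.73
DPL 62,Sagar,Fe,63.55
DPL 62,Sehore,Fe,65.26
DPL 62,Samastipore,Fe,70.38
DPL 62,Sabour,Fe,98.21
L 4596,Delhi,Fe,114.10
L 4596,Kanpur,Fe,80.01
L 4596,Sagar,Fe,76.57
L 4596,Sehore,Fe,66.77
L 4596,Samastipore,Fe,97.02
L 4596,Sabour,Fe,105.10
IPL 321,Delhi,Fe,87.43
IPL 321,Kanpur,Fe,66.32
IPL 321,Sagar,Fe,75.43
IPL 321,Sehore,Fe,60.93
IPL 321,Samastipore,Fe,87.46
IPL 321,Sabour,Fe,72.88
L 4147,Delhi,Fe,96.72
L 4147,Kanpur,Fe,96.30
L 4147,Sagar,Fe,87.71
L 4147,Sehore,Fe,100.29
L 4147,Samastipore,Fe,94.19
L 4147,Sabour,Fe,94.46
DPL 58,Delhi,Fe,64.68
DPL 58,Kanpur,Fe,57.09
DPL 58,Sagar,Fe,72.00
DPL 58,Sehore,Fe,53.90
DPL 58,Samastipore,Fe,75.21
DPL 58,Sabour,Fe,85.79
JL 3,Delhi,Fe,65.80
JL 3,Kanpur,Fe,56.89
JL 3,Sagar,Fe,73.42
JL 3,Sehore,Fe,71.65
JL 3,Samastipore,Fe,78.35
JL 3,Sabour,Fe,72.28
WBL 77,Delhi,Fe,62.89
WBL 77,Kanpur,Fe,50.61
WBL 77,Sagar,Fe,86.37
WBL 77,Sehore,Fe,75.11
WBL 77,Samastipore,Fe,76.10
WBL 77,Sabour,Fe,86.78
L 4076,Delhi,Fe,82.96
L 4076,Kanpur,Fe,77.98
L 4076,Sagar,Fe,75.43
L 4076,Sehore,Fe,71.38
L 4076,Samastipore,Fe,64.69
L 4076,Sabour,Fe,68.06
BM 4,Delhi,Fe,89.80
BM 4,Kanpur,Fe,55.48
BM 4,Sagar,Fe,86.51
BM 4,Sehore,Fe,65.27
BM 4,Samastipore,Fe,83.24
BM 4,Sabour,Fe,72.46
K 75,Delhi,Fe,82.66
K 75,Kanpur,Fe,68.21
K 75,Sagar,Fe,79.71
K 75,Sehore,Fe,73.95
K 75,Samastipore,Fe,82.02
K 75,Sabour,Fe,69.36
VL 520,Delhi,Fe,83.40
VL 520,Kanpur,Fe,60.11
VL 520,Sagar,Fe,74.11
VL 520,Sehore,Fe,55.68
VL 520,Samastipore,Fe,86.90
VL 520,Sabour,Fe,91.46
PL 7,Delhi,Fe,81.54
PL 7,Kanpur,Fe,51.39
PL 7,Sagar,Fe,69.93
PL 7,Sehore,Fe,73.70
PL 7,Samastipore,Fe,78.46
PL 7,Sabour,Fe,74.46
PL 6,Delhi,Fe,80.23
PL 6,Kanpur,Fe,49.90
PL 6,Sagar,Fe,94.13
PL 6,Sehore,Fe,74.35
PL 6,Samastipore,Fe,74.96
PL 6,Sabour,Fe,75.48
L 4717,Delhi,Fe,79.15
L 4717,Kanpur,Fe,55.46
L 4717,Sagar,Fe,76.32
L 4717,Sehore,Fe,74.65
L 4717,Samastipore,Fe,88.48
L 4717,Sabour,Fe,82.53
PL 406,Delhi,Fe,75.02
PL 406,Kanpur,Fe,52.40
PL 406,Sagar,Fe,69.47
PL 406,Sehore,Fe,68.14
PL 406,Samastipore,Fe,82.71
PL 406,Sabour,Fe,74.11
PL 639,Delhi,Fe,86.33
PL 639,Kanpur,Fe,57.86
PL 639,Sagar,Fe,67.76
PL 639,Sehore,Fe,60.69
PL 639,Samastipore,Fe,75.45
PL 639,Sabour,Fe,69.05
DPL 62,Delhi,Zn,54.70
DPL 62,Kanpur,Zn,53.42
DPL 62,Sagar,Zn,35.56
DPL 62,Sehore,Zn,46.19
DPL 62,Samastipore,Zn,34.96
DPL 62,Sabour,Zn,46.81
L 4596,Delhi,Zn,47.62
L 4596,Kanpur,Zn,36.66
L 4596,Sagar,Zn,66.29
L 4596,Sehore,Zn,42.31
L 4596,Samastipore,Zn,48.70
L 4596,Sabour,Zn,64.88
IPL 321,Delhi,Zn,66.35
IPL 321,Kanpur,Zn,21.90
IPL 321,Sagar,Zn,51.57
IPL 321,Sehore,Zn,53.45
IPL 321,Samastipore,Zn,52.19
IPL 321,Sabour,Zn,74.62
L 4147,Delhi,Zn,70.29
L 4147,Kanpur,Zn,53.93
L 4147,Sagar,Zn,64.24
L 4147,Sehore,Zn,60.91
L 4147,Samastipore,Zn,64.15
L 4147,Sabour,Zn,68.17
DPL 58,Delhi,Zn,66.76
DPL 58,Kanpur,Zn,38.29
DPL 58,Sagar,Zn,48.42
DPL 58,Sehore,Zn,48.40
DPL 58,Samastipore,Zn,35.91
DPL 58,Sabour,Zn,57.58
JL 3,Delhi,Zn,53.17
JL 3,Kanpur,Zn,52.60
JL 3,Sagar,Zn,53.91
JL 3,Sehore,Zn,45.61
JL 3,Samastipore,Zn,43.49
JL 3,Sabour,Zn,47.57
WBL 77,Delhi,Zn,42.44
WBL 77,Kanpur,Zn,32.53
WBL 77,Sagar,Zn,64.98
WBL 77,Sehore,Zn,55.78
WBL 77,Samastipore,Zn,32.46
WBL 77,Sabour,Zn,47.26
L 4076,Delhi,Zn,47.42
L 4076,Kanpur,Zn,47.43
L 4076,Sagar,Zn,46.78
L 4076,Sehore,Zn,25.65
L 4076,Samastipore,Zn,38.02
L 4076,Sabour,Zn,44.18
BM 4,Delhi,Zn,67.73
BM 4,Kanpur,Zn,34.73
BM 4,Sagar,Zn,52.69
BM 4,Sehore,Zn,52.43
BM 4,Samastipore,Zn,52.81
BM 4,Sabour,Zn,43.86
K 75,Delhi,Zn,38.94
K 75,Kanpur,Zn,47.15
K 75,Sagar,Zn,49.32
K 75,Sehore,Zn,45.78
K 75,Samastipore,Zn,42.21
K 75,Sabour,Zn,39.88
VL 520,Delhi,Zn,58.32
VL 520,Kanpur,Zn,63.92
VL 520,Sagar,Zn,38.15
VL 520,Sehore,Zn,32.65
VL 520,Samastipore,Zn,40.03
VL 520,Sabour,Zn,50.01
PL 7,Delhi,Zn,44.92
PL 7,Kanpur,Zn,25.16
PL 7,Sagar,Zn,54.50
PL 7,Sehore,Zn,53.40
PL 7,Samastipore,Zn,45.55
PL 7,Sabour,Zn,54.51
PL 6,Delhi,Zn,38.96
PL 6,Kanpur,Zn,30.18
PL 6,Sagar,Zn,63.68
PL 6,Sehore,Zn,50.73
PL 6,Samastipore,Zn,57.39
PL 6,Sabour,Zn,43.81
L 4717,Delhi,Zn,49.23
L 4717,Kanpur,Zn,35.26
L 4717,Sagar,Zn,51.68
L 4717,Sehore,Zn,46.43
L 4717,Samastipore,Zn,44.13
L 4717,Sabour,Zn,61.61
PL 406,Delhi,Zn,46.69
PL 406,Kanpur,Zn,46.25
PL 406,Sagar,Zn,49.44
PL 406,Sehore,Zn,41.20
PL 406,Samastipore,Zn,64.72
PL 406,Sabour,Zn,49.54
PL 639,Delhi,Zn,68.24
PL 639,Kanpur,Zn,24.25
PL 639,Sagar,Zn,49.61
PL 639,Sehore,Zn,47.07
PL 639,Samastipore,Zn,45.97
PL 639,Sabour,Zn,72.99
DPL 62,Delhi,PA,1.08
DPL 62,Kanpur,PA,1.41
DPL 62,Sagar,PA,1.47
DPL 62,Sehore,PA,1.48
DPL 62,Samastipore,PA,1.27
DPL 62,Sabour,PA,1.23
L 4596,Delhi,PA,2.49
L 4596,Kanpur,PA,2.52
L 4596,Sagar,PA,2.65
L 4596,Sehore,PA,2.82
L 4596,Samastipore,PA,2.47
L 4596,Sabour,PA,2.42
IPL 321,Delhi,PA,1.03
IPL 321,Kanpur,PA,1.83
IPL 321,Sagar,PA,1.31
IPL 321,Sehore,PA,1.61
IPL 321,Samastipore,PA,1.18
IPL 321,Sabour,PA,1.06
L 4147,Delhi,PA,2.57
L 4147,Kanpur,PA,2.79
L 4147,Sagar,PA,2.62
L 4147,Sehore,PA,2.61
L 4147,Samastipore,PA,2.57
L 4147,Sabour,PA,2.54
DPL 58,Delhi,PA,1.25
DPL 58,Kanpur,PA,1.49
DPL 58,Sagar,PA,1.69
DPL 58,Sehore,PA,1.75
DPL 58,Samastipore,PA,1.25
DPL 58,Sabour,PA,1.29
JL 3,Delhi,PA,0.94
JL 3,Kanpur,PA,1.49
JL 3,Sagar,PA,2.11
JL 3,Sehore,PA,1.21
JL 3,Samastipore,PA,0.94
JL 3,Sabour,PA,1.47
WBL 77,Delhi,PA,1.96
WBL 77,Kanpur,PA,1.96
WBL 77,Sagar,PA,1.96
WBL 77,Sehore,PA,2.64
WBL 77,Samastipore,PA,1.79
WBL 77,Sabour,PA,1.67
L 4076,Delhi,PA,1.52
L 4076,Kanpur,PA,1.79
L 4076,Sagar,PA,1.82
L 4076,Sehore,PA,1.89
L 4076,Samastipore,PA,1.52
L 4076,Sabour,PA,1.52
BM 4,Delhi,PA,1.15
BM 4,Kanpur,PA,1.78
BM 4,Sagar,PA,1.45
BM 4,Sehore,PA,1.42
BM 4,Samastipore,PA,1.26
BM 4,Sabour,PA,1.25
K 75,Delhi,PA,0.76
K 75,Kanpur,PA,0.98
K 75,Sagar,PA,0.95
K 75,Sehore,PA,1.13
K 75,Samastipore,PA,0.76
K 75,Sabour,PA,0.93
VL 520,Delhi,PA,0.92
VL 520,Kanpur,PA,1.79
VL 520,Sagar,PA,1.24
VL 520,Sehore,PA,1.30
VL 520,Samastipore,PA,1.30
VL 520,Sabour,PA,0.98
PL 7,Delhi,PA,2.71
PL 7,Kanpur,PA,2.71
PL 7,Sagar,PA,2.71
PL 7,Sehore,PA,2.84
PL 7,Samastipore,PA,2.71
PL 7,Sabour,PA,2.71
PL 6,Delhi,PA,1.06
PL 6,Kanpur,PA,1.06
PL 6,Sagar,PA,1.28
PL 6,Sehore,PA,1.35
PL 6,Samastipore,PA,1.18
PL 6,Sabour,PA,1.22
L 4717,Delhi,PA,1.16
L 4717,Kanpur,PA,1.16
L 4717,Sagar,PA,1.43
L 4717,Sehore,PA,1.34
L 4717,Samastipore,PA,1.34
L 4717,Sabour,PA,1.31
PL 406,Delhi,PA,2.20
PL 406,Kanpur,PA,2.23
PL 406,Sagar,PA,2.61
PL 406,Sehore,PA,2.01
PL 406,Samastipore,PA,2.55
PL 406,Sabour,PA,2.20
PL 639,Delhi,PA,2.46
PL 639,Kanpur,PA,2.68
PL 639,Sagar,PA,2.55
PL 639,Sehore,PA,2.52
PL 639,Samastipore,PA,2.54
PL 639,Sabour,PA,2.43
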