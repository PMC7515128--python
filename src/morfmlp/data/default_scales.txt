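# Default amino-acid scale tables shipped with morf-mlp.
# 13 physicochemical scales (AAindex accessions) followed by two
# structural propensity scales (missing-density REMARK465 and
# Deleage/Roux coil propensities). One block per scale: a ">name"
# line followed by 20 "letter value" lines. Replace with
# `morf-mlp ... --scales FILE` to use a different set.
>KYTJ820101 hydropathy (Kyte-Doolittle)
A 1.8
R -4.5
N -3.5
D -3.5
C 2.5
Q -3.5
E -3.5
G -0.4
H -3.2
I 4.5
L 3.8
K -3.9
M 1.9
F 2.8
P -1.6
S -0.8
T -0.7
W -0.9
Y -1.3
V 4.2
>HOPT810101 hydrophilicity (Hopp-Woods)
A -0.5
R 3.0
N 0.2
D 3.0
C -1.0
Q 0.2
E 3.0
G 0.0
H -0.5
I -1.8
L -1.8
K 3.0
M -1.3
F -2.5
P 0.0
S 0.3
T -0.4
W -3.4
Y -2.3
V -1.5
>EISD840101 consensus hydrophobicity (Eisenberg)
A 0.62
R -2.53
N -0.78
D -0.90
C 0.29
Q -0.85
E -0.74
G 0.48
H -0.40
I 1.38
L 1.06
K -1.50
M 0.64
F 1.19
P 0.12
S -0.18
T -0.05
W 0.81
Y 0.26
V 1.08
>GRAR740102 polarity (Grantham)
A 8.1
R 10.5
N 11.6
D 13.0
C 5.5
Q 10.5
E 12.3
G 9.0
H 10.4
I 5.2
L 4.9
K 11.3
M 5.7
F 5.2
P 8.0
S 9.2
T 8.6
W 5.4
Y 6.2
V 5.9
>ZIMJ680104 isoelectric point
A 6.00
R 10.76
N 5.41
D 2.77
C 5.05
Q 5.65
E 3.22
G 5.97
H 7.59
I 6.02
L 5.98
K 9.74
M 5.74
F 5.48
P 6.30
S 5.68
T 5.66
W 5.89
Y 5.66
V 5.96
>KLEP840101 net charge
A 0.0
R 1.0
N 0.0
D -1.0
C 0.0
Q 0.0
E -1.0
G 0.0
H 0.0
I 0.0
L 0.0
K 1.0
M 0.0
F 0.0
P 0.0
S 0.0
T 0.0
W 0.0
Y 0.0
V 0.0
>FAUJ880103 normalized van der Waals volume
A 1.00
R 6.13
N 2.95
D 2.78
C 2.43
Q 3.95
E 3.78
G 0.00
H 4.66
I 4.00
L 4.00
K 4.77
M 4.43
F 5.89
P 2.72
S 1.60
T 2.60
W 8.08
Y 6.47
V 3.00
>CHOP780201 alpha-helix propensity (Chou-Fasman)
A 1.42
R 0.98
N 0.67
D 1.01
C 0.70
Q 1.11
E 1.51
G 0.57
H 1.00
I 1.08
L 1.21
K 1.16
M 1.45
F 1.13
P 0.57
S 0.77
T 0.83
W 1.08
Y 0.69
V 1.06
>CHOP780202 beta-sheet propensity (Chou-Fasman)
A 0.83
R 0.93
N 0.89
D 0.54
C 1.19
Q 1.10
E 0.37
G 0.75
H 0.87
I 1.60
L 1.30
K 0.74
M 1.05
F 1.38
P 0.55
S 0.75
T 1.19
W 1.37
Y 1.47
V 1.70
>CHOP780203 beta-turn propensity (Chou-Fasman)
A 0.66
R 0.95
N 1.56
D 1.46
C 1.19
Q 0.98
E 0.74
G 1.56
H 0.95
I 0.47
L 0.59
K 1.01
M 0.60
F 0.60
P 1.52
S 1.43
T 0.96
W 0.96
Y 1.14
V 0.50
>BHAR880101 flexibility (Bhaskaran-Ponnuswamy)
A 0.357
R 0.529
N 0.463
D 0.511
C 0.346
Q 0.493
E 0.497
G 0.544
H 0.323
I 0.462
L 0.365
K 0.466
M 0.295
F 0.314
P 0.509
S 0.507
T 0.444
W 0.305
Y 0.420
V 0.386
>JANJ780101 average accessible surface area
A 27.8
R 94.7
N 60.1
D 60.6
C 15.5
Q 68.7
E 68.2
G 24.5
H 50.7
I 22.8
L 27.6
K 103.0
M 33.5
F 25.5
P 51.5
S 42.0
T 45.0
W 34.7
Y 55.2
V 23.7
>CHAM820101 polarizability (Charton-Charton)
A 0.046
R 0.291
N 0.134
D 0.105
C 0.128
Q 0.180
E 0.151
G 0.000
H 0.230
I 0.186
L 0.186
K 0.219
M 0.221
F 0.290
P 0.131
S 0.062
T 0.108
W 0.409
Y 0.298
V 0.140
>REMARK465 missing-density propensity
A 0.06
R 0.18
N 0.25
D 0.28
C -0.72
Q 0.31
E 0.33
G 0.28
H -0.08
I -0.49
L -0.38
K 0.30
M -0.23
F -0.53
P 0.45
S 0.34
T 0.12
W -0.58
Y -0.51
V -0.42
>DELEAGE_ROUX coil propensity
A 0.90
R 1.02
N 1.30
D 1.22
C 0.95
Q 1.02
E 0.91
G 1.52
H 0.96
I 0.68
L 0.74
K 1.03
M 0.80
F 0.79
P 1.42
S 1.29
T 1.09
W 0.92
Y 1.07
V 0.67
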