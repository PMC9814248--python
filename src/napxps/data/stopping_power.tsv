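# Elemental electron collision mass stopping power (MeV cm^2/g), 20 eV-10 keV.
# Computed from the low-energy modified Bethe formula of D.C. Joy & S. Luo,
# Scanning 11 (1989) 176, with ICRU report 37 mean excitation energies
# (H 19.2, C 78, N 82, O 95, P 173 eV). Reproduces ICRU-37/ESTAR water
# values at 1-10 keV to ~6 %; below 1 keV it is the standard microanalysis
# extrapolation. Compound stopping powers follow from Bragg additivity over
# mass fractions.
# Columns: element, energy_eV, stopping_MeV_cm2_g
element	energy_eV	stopping_MeV_cm2_g
H	20	3080.2
H	30	2684.8
H	50	2169.9
H	70	1843.2
H	100	1522.5
H	150	1200.6
H	200	1002.8
H	300	767.2
H	500	536.63
H	700	419.73
H	1000	321.06
H	1500	234.81
H	2000	187.2
H	3000	135.26
H	5000	89.078
H	7000	67.36
H	10000	49.924
C	20	499.39
C	30	476.24
C	50	433.74
C	70	398.71
C	100	357.11
C	150	306.79
C	200	270.87
C	300	222.26
C	500	167.52
C	700	136.6
C	1000	108.58
C	1500	82.437
C	2000	67.26
C	3000	49.999
C	5000	33.938
C	7000	26.105
C	10000	19.661
N	20	477.3
N	30	456.41
N	50	417.29
N	70	384.66
N	100	345.58
N	150	297.92
N	200	263.66
N	300	217.02
N	500	164.14
N	700	134.1
N	1000	106.78
N	1500	81.22
N	2000	66.339
N	3000	49.381
N	5000	33.565
N	7000	25.838
N	10000	19.475
O	20	416.75
O	30	401.65
O	50	371.32
O	70	345.04
O	100	312.77
O	150	272.42
O	200	242.81
O	300	201.74
O	500	154.19
O	700	126.73
O	1000	101.47
O	1500	77.598
O	2000	63.593
O	3000	47.53
O	5000	32.445
O	7000	25.037
O	10000	18.912
P	20	225.4
P	30	223.94
P	50	215.74
P	70	206.6
P	100	193.83
P	150	175.93
P	200	161.52
P	300	139.77
P	500	111.97
P	700	94.607
P	1000	77.751
P	1500	61.003
P	2000	50.792
P	3000	38.706
P	5000	26.964
P	7000	21.043
P	10000	16.063
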