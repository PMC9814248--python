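# Elemental photoabsorption mass attenuation coefficients mu/rho (cm^2/g).
# Assembled from standard published compilations: B.L. Henke, E.M. Gullikson,
# J.C. Davis, At. Data Nucl. Data Tables 54 (1993) 181 (100 eV - 2 keV) and
# NIST XCOM (photoelectric component, 2 - 10 keV). Values are rounded to
# about two significant figures (~10 % accuracy class); absorption-edge fine
# structure (notably the P L edges below 200 eV) is smoothed. Photoabsorption
# only; coherent/incoherent scattering is intentionally excluded (it is a
# <5 % correction below 4 keV for these light elements).
# Intended use: linear attenuation of keV x-rays in layered slab estimates.
# Columns: element, energy_eV, mu_over_rho_cm2_g
element	energy_eV	mu_over_rho_cm2_g
H	100	1.37e+04
H	200	1380
H	300	360
H	500	67
H	700	22
H	1000	6.8
H	1486.6	1.85
H	2000	0.7
H	3000	0.185
H	5000	0.034
H	10000	0.0036
C	100	3.6e+04
C	150	1.9e+04
C	200	1.05e+04
C	250	6300
C	284	4600
C	284.4	7.8e+04
C	300	6.9e+04
C	400	3.2e+04
C	500	1.9e+04
C	700	7600
C	1000	2150
C	1200	1270
C	1486.6	700
C	2000	290
C	3000	88
C	4000	37
C	6000	10.5
C	8000	4.3
C	10000	2.1
N	100	1.6e+04
N	150	9000
N	200	6200
N	300	4000
N	409.7	2700
N	410.1	4.4e+04
N	500	2.45e+04
N	700	9200
N	1000	3250
N	1200	1930
N	1486.6	1090
N	2000	455
N	3000	140
N	4000	60
N	6000	18
N	8000	7.5
N	10000	3.7
O	100	2.1e+04
O	150	1.2e+04
O	200	8300
O	300	5300
O	400	3700
O	542.9	2600
O	543.3	2.65e+04
O	700	1.27e+04
O	1000	4500
O	1200	2660
O	1486.6	1570
O	2000	660
O	3000	205
O	4000	88
O	6000	27
O	8000	11.2
O	10000	5.6
P	100	2e+04
P	135	6.5e+04
P	150	6e+04
P	200	4.7e+04
P	300	4.5e+04
P	500	1.2e+04
P	700	5000
P	1000	2100
P	1200	1240
P	1486.6	700
P	2000	325
P	2145.3	270
P	2145.7	2450
P	3000	980
P	4000	445
P	6000	145
P	8000	65
P	10000	35
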