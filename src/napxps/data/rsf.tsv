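# Default relative sensitivity factors for Al K-alpha (1486.6 eV) XPS
# quantification, normalized to C1s = 1.00.
# Derived from the photoionization cross-section compilation of
# J.H. Scofield, J. Electron Spectrosc. Relat. Phenom. 8 (1976) 129
# (theoretical subshell cross sections at 1487 eV). P2p is the summed
# 2p3/2 + 2p1/2 doublet. No analyzer transmission-function correction is
# applied; replace this table with an instrument-specific one for
# quantitative work on measured spectra.
# Columns: line, rsf
line	rsf
C1s	1.00
N1s	1.80
O1s	2.93
P2p	1.19
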