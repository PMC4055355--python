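# Internal-coordinate template for the R1 (MTSSL-cysteine) side chain.
# Rigid bond lengths/angles; only the five linker dihedrals chi1-chi5 vary.
# atom  parent  grand  ggrand  bond(A)  angle(deg)  dihedral(deg|chiN)
atom SG  CB  CA  N    1.810  114.0  chi1
atom SD  SG  CB  CA   2.030  104.0  chi2
atom CE  SD  SG  CB   1.810  104.0  chi3
atom C3  CE  SD  SG   1.500  114.0  chi4
atom C4  C3  CE  SD   1.350  126.0  chi5
atom C5  C4  C3  CE   1.500  112.0  180.0
atom N1  C5  C4  C3   1.470  104.0  0.0
atom C9  N1  C5  C4   1.470  112.0  0.0
atom O1  N1  C5  C4   1.280  122.0  180.0
atom C6  C5  C4  C3   1.520  110.0  122.0
atom C7  C5  C4  C3   1.520  110.0  -122.0
atom C8  C9  N1  C5   1.520  110.0  122.0
# chi-angle definitions (standard R1 convention; chi5 fourth atom is
# convention-dependent and configurable at run time)
chi 1  N   CA  CB  SG
chi 2  CA  CB  SG  SD
chi 3  CB  SG  SD  CE
chi 4  SG  SD  CE  C3
chi 5  SD  CE  C3  C4
# spin-center rule options: N1 atom or N1-O1 midpoint
spin_center N1 O1
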