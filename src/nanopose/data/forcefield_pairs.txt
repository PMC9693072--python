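# Lennard-Jones pair parameters for drug-element / graphene-carbon pairs.
# Columns: element_i element_j sigma(Angstrom) epsilon(eV)
# Pair values built from UFF per-element parameters by the Lorentz-Berthelot
# mixing rule sigma_ij = (sigma_i + sigma_j)/2, eps_ij = sqrt(eps_i * eps_j).
C C 3.8510 4.5150e-3
C O 3.6755 3.4130e-3
C H 3.3685 2.9227e-3
C N 3.7555 3.6601e-3
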