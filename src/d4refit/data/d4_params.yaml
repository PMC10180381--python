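# Effective two-body dispersion parameters for water (H, O).
#
# Functional rows carry the published D4 Becke-Johnson damping defaults
# (s6, s8 dimensionless; a1 dimensionless; a2 in bohr). q_factor is the
# multipole ratio Q_a (bohr^2) entering the C8 recursion
# C8_ab = 3 * C6_ab * sqrt(Q_a * Q_b). Pair C6 values (hartree*bohr^6)
# are fixed effective coefficients representative of water; this package
# deliberately omits charge/coordination dependence, so per-structure
# components computed by an external dispersion code can be ingested
# instead whenever exact coefficients matter.
units:
  c6: hartree_bohr6      # or kcalmol_angstrom6
  q_factor: bohr2        # or angstrom2
  a2: bohr               # or angstrom
elements:
  H: {q_factor: 4.0295}
  O: {q_factor: 6.7268}
pairs:
  H-H: 3.0884
  H-O: 5.7385
  O-O: 10.3708
functionals:
  blyp:    {s6: 1.0, s8: 2.34076671, a1: 0.44488865, a2: 4.09330090}
  b3lyp:   {s6: 1.0, s8: 2.02929367, a1: 0.40868035, a2: 4.53807137}
  pbe:     {s6: 1.0, s8: 0.95948085, a1: 0.38574991, a2: 4.80688534}
  pbe0:    {s6: 1.0, s8: 1.20065498, a1: 0.40085597, a2: 5.02928789}
  revpbe:  {s6: 1.0, s8: 1.74676957, a1: 0.53634900, a2: 3.07261485}
  revpbe0: {s6: 1.0, s8: 1.57185414, a1: 0.38705966, a2: 4.11028876}
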