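# Default chemistry tables.
#
# vdw_by_element: Bondi van der Waals radii [Angstrom].
# mass_by_element: standard atomic weights [Da].
# hi_by_element / hi_overrides: rule-based binary atomic hydropathicity
#   (+0.5 hydrophobic, -0.5 hydrophilic).  Element defaults are refined by
#   (residue, atom-name) overrides for polar hydrogens and for carbonyl /
#   carboxylate / amide / guanidinium carbons.  The residue key "*" applies
#   to every residue.  All three tables can be overridden from user config.
vdw_by_element:
  H: 1.20
  D: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  F: 1.47
  CL: 1.75
  BR: 1.85
  I: 1.98
  SE: 1.90
  B: 1.92
  NA: 2.27
  MG: 1.73
  K: 2.75
  CA: 2.31
  MN: 2.05
  FE: 2.05
  CO: 2.00
  NI: 1.97
  CU: 1.96
  ZN: 1.39
mass_by_element:
  H: 1.008
  D: 2.014
  C: 12.011
  N: 14.007
  O: 15.999
  S: 32.06
  P: 30.974
  F: 18.998
  CL: 35.45
  BR: 79.904
  I: 126.904
  SE: 78.971
  B: 10.81
  NA: 22.990
  MG: 24.305
  K: 39.098
  CA: 40.078
  MN: 54.938
  FE: 55.845
  CO: 58.933
  NI: 58.693
  CU: 63.546
  ZN: 65.38
hi_by_element:
  H: 0.5
  D: 0.5
  C: 0.5
  S: 0.5
  SE: 0.5
  N: -0.5
  O: -0.5
  P: -0.5
  F: -0.5
  CL: -0.5
  BR: -0.5
  I: -0.5
  B: 0.5
  NA: -0.5
  MG: -0.5
  K: -0.5
  CA: -0.5
  MN: -0.5
  FE: -0.5
  CO: -0.5
  NI: -0.5
  CU: -0.5
  ZN: -0.5
hi_overrides:
  "*":           # backbone amide / terminal amine hydrogens and carbonyl C
    H: -0.5
    H1: -0.5
    H2: -0.5
    H3: -0.5
    HN: -0.5
    C: -0.5
    OXT: -0.5
  SER: {HG: -0.5}
  THR: {HG1: -0.5}
  TYR: {HH: -0.5}
  CYS: {HG: -0.5}
  ASP: {CG: -0.5}
  GLU: {CD: -0.5}
  ASN: {CG: -0.5, HD21: -0.5, HD22: -0.5}
  GLN: {CD: -0.5, HE21: -0.5, HE22: -0.5}
  ARG: {CZ: -0.5, HE: -0.5, HH11: -0.5, HH12: -0.5, HH21: -0.5, HH22: -0.5}
  LYS: {HZ1: -0.5, HZ2: -0.5, HZ3: -0.5}
  HIS: {HD1: -0.5, HE2: -0.5}
  HSD: {HD1: -0.5, HE2: -0.5}
  HSE: {HD1: -0.5, HE2: -0.5}
  TRP: {HE1: -0.5}
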