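# Charge/radius parameter table used when reading PDB files (which carry
# neither).  Radii are per element; charges are per residue/atom and
# realize the default protonation form of each titratable residue class
# (Asp/Glu deprotonated, His neutral, Lys protonated), with the full
# +-1 e localized on the titratable functional-group atom(s).
# Everything here is user-overridable; PQR input bypasses this table.
radii:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  NA: 1.36
  CL: 1.81
  K: 1.76
  CA: 1.37
  MG: 1.18
charges:
  ASP: {CG: -1.0}
  GLU: {CD: -1.0}
  HIS: {ND1: 0.0, NE2: 0.0}
  LYS: {NZ: 1.0}
  ARG: {CZ: 1.0}
  NA: {NA: 1.0}
  SOD: {SOD: 1.0}
  CL: {CL: -1.0}
  CLA: {CLA: -1.0}
  CA: {CA: 2.0}
  CAL: {CAL: 2.0}
  MG: {MG: 2.0}
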