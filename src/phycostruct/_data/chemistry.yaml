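# Chemistry reference data for surface, contact and substitution analysis.

# van der Waals radii (Angstrom), Bondi-style set commonly used for
# solvent-accessible surface calculations on protein crystal structures.
vdw_radii:
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  H: 1.20
  SE: 1.90
default_radius: 1.70

probe_radius: 1.4
sasa_points: 960

# Mean amino-acid residue volumes (Angstrom^3), Zamyatnin-style table.
# Used for the steric-complementarity evidence of compensatory substitutions.
residue_volumes:
  A: 88.6
  R: 173.4
  N: 114.1
  D: 111.1
  C: 108.5
  Q: 143.8
  E: 138.4
  G: 60.1
  H: 153.2
  I: 166.7
  L: 166.7
  K: 168.6
  M: 162.9
  F: 189.9
  P: 112.7
  S: 89.0
  T: 116.1
  W: 227.8
  Y: 193.6
  V: 140.0

# Apolar side-chain carbons per residue type (hydrophobic-contact detection).
# CB of polar residues is included where it is a genuine aliphatic carbon.
apolar_atoms:
  ALA: [CB]
  ARG: [CB, CG]
  ASN: [CB]
  ASP: [CB]
  CYS: [CB]
  GLN: [CB, CG]
  GLU: [CB, CG]
  HIS: [CB]
  ILE: [CB, CG1, CG2, CD1]
  LEU: [CB, CG, CD1, CD2]
  LYS: [CB, CG, CD]
  MET: [CB, CG, CE]
  PHE: [CB, CG, CD1, CD2, CE1, CE2, CZ]
  PRO: [CB, CG, CD]
  SER: [CB]
  THR: [CG2]
  TRP: [CB, CG, CD1, CD2, CE2, CE3, CZ2, CZ3, CH2]
  TYR: [CB, CG, CD1, CD2, CE1, CE2]
  VAL: [CB, CG1, CG2]

# Average residue masses (Da) for mass-from-sequence calculations
# (monoisotopic precision is unnecessary for Matthews-coefficient work).
residue_masses:
  A: 71.0788
  R: 156.1875
  N: 114.1038
  D: 115.0886
  C: 103.1388
  E: 129.1155
  Q: 128.1307
  G: 57.0519
  H: 137.1411
  I: 113.1594
  L: 113.1594
  K: 128.1741
  M: 131.1926
  F: 147.1766
  P: 97.1167
  S: 87.0782
  T: 101.1051
  W: 186.2132
  Y: 163.1760
  V: 99.1326
water_mass: 18.01528

# Formula masses (Da) of common bilin components, used when adding covalently
# bound chromophores to an asymmetric-unit mass.
ligand_masses:
  CYC: 586.68
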