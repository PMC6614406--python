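# Ring/bridge atom naming tables for bilin chromophore components.
#
# Atom names follow the PDB chemical-component convention for open-chain
# tetrapyrroles: pyrrole rings A-D, ring atoms C1x..C4x + Nx, methine bridge
# carbons CHB (A-B), CHC (B-C), CHD (C-D).  Ring A carries the thioether
# attachment carbon (CAA) that bonds the conserved cysteine SG.  Because
# deposited entries occasionally deviate from the reference component, every
# field here can be overridden from a user config file.
#
# Torsion quadruples per methine bridge:
#   config  — torsion about the (formal) methine double bond, |t| <= 90 -> Z
#   rotamer — torsion about the methine single bond,           |t| <= 90 -> syn
CYC:
  rings:
    A: [NA, C1A, C2A, C3A, C4A]
    B: [NB, C1B, C2B, C3B, C4B]
    C: [NC, C1C, C2C, C3C, C4C]
    D: [ND, C1D, C2D, C3D, C4D]
  bridges:
    AB: CHB
    BC: CHC
    CD: CHD
  # pi-conjugated system: rings B, C, D plus the BC and CD methines; ring A
  # is sp3-linked and excluded.
  conjugated:
    [NB, C1B, C2B, C3B, C4B, CHC, NC, C1C, C2C, C3C, C4C, CHD,
     ND, C1D, C2D, C3D, C4D]
  attachment_atom: CAA
  torsions:
    AB:
      config:  [C3A, C4A, CHB, C1B]
      rotamer: [C4A, CHB, C1B, NB]
    BC:
      config:  [C3B, C4B, CHC, C1C]
      rotamer: [C4B, CHC, C1C, NC]
    CD:
      config:  [C3C, C4C, CHD, C1D]
      rotamer: [C4C, CHD, C1D, ND]
  # apolar (carbon) atoms used for hydrophobic-contact detection: ring and
  # bridge carbons plus methyl/vinyl substituents; propionate and carbonyl
  # carbons excluded.
  apolar_atoms:
    [C1A, C2A, C3A, C4A, C1B, C2B, C3B, C4B, C1C, C2C, C3C, C4C,
     C1D, C2D, C3D, C4D, CHB, CHC, CHD, CMA, CMB, CMC, CMD,
     CAA, CBA, CAD, CBD]
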