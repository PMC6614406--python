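# phycostruct

Structural and spectral analysis of phycobiliproteins — the water-soluble
light-harvesting proteins of cyanobacteria and red algae that carry
covalently bound open-chain tetrapyrrole (bilin) chromophores.

Phycocyanin assembles hierarchically: an αβ heterodimer ("monomer"), the
(αβ)₃ trimer, and the doughnut-shaped (αβ)₆ hexamer.  Each α-subunit binds
one phycocyanobilin (PCB) at Cys84; each β-subunit binds two, at Cys82 and
Cys153.  The absorption maximum of each protein-bound bilin tracks the
effective length of its π-conjugated system, which depends on how coplanar
the B, C and D pyrrole rings remain: a larger deviation angle between
adjacent ring planes shortens the conjugation and blue-shifts the
absorbance.  `phycostruct` makes every step of that structural argument
recomputable from deposited coordinates, and every stage testable on
synthetic fixtures with known ground truth.

## What it computes

Given a crystal structure (PDB or mmCIF):

- **Chromophore geometry** — total least-squares planes through each
  5-atom pyrrole ring; the acute inter-ring deviation angles
  `θ_XY = arccos |n_X · n_Y|`; Z/E and syn/anti classification of each
  methine bridge from its double- and single-bond torsions
  (the canonical protein-bound conformation is *anti-syn-anti*).
- **Assembly analysis** — αβ monomer pairing and trimer/hexamer grouping
  from inter-chain contacts; the closest centre–centre distance between
  chromophores per assembly level and pair class (the energy-transfer
  geometry: >35 Å within a monomer, ~20–25 Å after oligomerisation).
- **Interface burial** — Shrake–Rupley-style solvent-accessible surface
  area (deterministic golden-spiral sampling, Bondi-type radii, 1.4 Å
  probe); buried area = SASA(A) + SASA(B) − SASA(A∪B).
- **Crystal solvent content** — Matthews coefficient
  `V_M = V_cell / (Z · M_asu)` and solvent fraction
  `1 − 1.230/V_M`, with the ASU mass derived from sequences and
  bound-ligand counts.
- **Contacts** — heavy-atom hydrogen bonds (N/O/S pairs ≤ 3.5 Å),
  hydrophobic contacts between apolar carbons (≤ 4.5 Å) and
  binding-pocket enumeration.
- **Substitution analysis** — conserved-position substitutions from a
  multiple sequence alignment, mapping onto author residue numbering with
  a hard guard against numbering drift, and detection of spatially
  compensatory substitution pairs (side chains ≤ 6 Å, annotated by gained
  hydrogen bonds or steric volume complementarity).
- **Spectral deconvolution** — smoothed-derivative band detection and
  constrained multi-start least-squares fitting of
  `A(λ) = b + Σᵢ aᵢ exp(−(λ−cᵢ)²/2wᵢ²)`, with automatic component-count
  selection and per-component shift comparison between proteins.

A deterministic synthetic-data module (`phycostruct.synthetic`) generates
every input class with a machine-readable manifest of the planted ground
truth; the closure of generator → analysis is the backbone of the test
suite.

## Worked example

Generate a synthetic hexamer whose eighteen chromophore centroids are
planted at the published assembly geometry, then tabulate the closest
distances:

```
$ phycostruct simulate assembly --seed 1 --out fixtures
$ phycostruct distances fixtures/assembly.pdb --out run1
{
  "distance_table": {
    "monomer": {
      "alpha84-beta82": 50.9,
      "beta82-beta153": 38.7,
      "beta153-alpha84": 50.0,
      "inter-alpha84": "exceeds_cap",
      ...
    },
    "trimer":  { "alpha84-beta82": 20.2, "inter-beta82": 33.3, ... },
    "hexamer": { "inter-alpha84": 26.8, "inter-beta82": 33.3,
                 "inter-beta153": 27.5, ... }
  }
}
```

Within one monomer every chromophore pair is ≥ 38 Å apart — too far for
efficient excitation-energy transfer — while trimer formation brings the
α84 bilin of one monomer within 20.2 Å of a neighbour's β82 bilin, and the
hexamer adds 26.8–27.5 Å inter-site routes.  Cells printed `exceeds_cap`
lie beyond the 51 Å reporting cap.

Deconvolve a synthetic three-band absorbance spectrum (0.5 % noise):

```
$ phycostruct simulate spectrum --seed 1 --out fixtures
$ phycostruct deconvolve fixtures/spectrum.csv --components 3 --seed 0 --out run2
{
  "deconvolve": {
    "n_components": 3,
    "centers_nm": [577.7, 606.78, 625.86],
    ...
  }
}
```

The fitted centres recover the planted band maxima (578, 607, 626 nm) to
well under a nanometre; component tables and the fitted curve are written
as TSV/CSV into the output directory.

To analyse a real deposited entry, fetch its coordinate file yourself
(nothing is ever downloaded) and run the one-shot workflow:

```
$ phycostruct reproduce /path/to/entry.pdb --config myrun.yaml --out results
```

which executes census, geometry, distances, interface and contact stages
(plus substitutions/deconvolution when the config provides alignments or a
spectrum) and writes one `summary.json` keyed by quantity.

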