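# Methods

This note documents the models, conventions and numerical choices behind
`phycostruct`, and what the synthetic fixtures do and do not establish
about real data.

## Coordinate model and chromophore extraction

Structures are parsed with gemmi (PDB v3.3 and mmCIF) into a flat typed
atom list grouped by chain.  Author chain/residue numbering is used
throughout so that positions quoted in the phycobiliprotein literature
(α84, β82, β153, …) match directly.  Alternate conformations are reduced
to the highest-occupancy conformer.  Waters are retained for census
purposes and excluded from chromophore, contact and surface logic.

Bilin atom naming follows the PDB chemical-component convention for the
phycocyanobilin component (`CYC`): pyrrole rings A–D with atoms
`C1x…C4x, Nx`, methine bridge carbons `CHB/CHC/CHD`, and the ring-A
thioether substituent carbon `CAA`.  Because deposited entries
occasionally deviate from the reference component, the whole table —
ring groups, bridge atoms, conjugated-atom list, attachment atom, torsion
quadruples, apolar-atom list — ships as editable YAML data and can be
overridden per run.  Attachment is detected geometrically: the nearest
cysteine SG within 2.1 Å of the ring-A substituent carbon.  A chromophore
with a missing named atom is flagged incomplete and excluded from
geometry statistics rather than silently skipped.

## Ring-plane geometry

Each ring plane is fitted to exactly its five ring atoms (pyrrole N +
four carbons) by total least squares (SVD of the centred coordinates);
exocyclic substituents are excluded, matching common practice for
reporting bilin ring-plane angles.  The deviation-from-coplanarity angle
between adjacent rings is the acute angle `arccos |n₁·n₂|`; "deviation"
is unsigned, so angles live in [0°, 90°].  The normal's sign is fixed
deterministically (positive component along +z, falling back to +y, +x),
which makes plane fits reproducible but never affects the angles.

Site statistics (mean ± sd of the B–C angle per attachment class) are
taken over the crystallographically independent chromophore copies of
one structure, reading a published "mean ± sd" as a spread over copies
rather than a fit uncertainty — the only reading that can be recomputed
from coordinates alone.

Methine bridges are classified from two torsions whose atom quadruples
ship with the ligand table: the configuration torsion about the formal
double bond (`C3X–C4X–CHY–C1Y`; |t| ≤ 90° → Z) and the rotamer torsion
about the single bond (`C4X–CHY–C1Y–NY`; |t| ≤ 90° → syn).  The summary
string joins the single-bond rotamers A→D (e.g. `anti-syn-anti`, the
extended conformation of protein-bound bilins).  Torsions follow the
IUPAC sign convention and are cross-checked in the tests against an
independent implementation (biotite).

## Assembly analysis

Chain typing is inferred from the chromophore census (one bilin → α-type,
two → β-type).  Monomers are paired by maximal inter-chain heavy-atom
contact count at 4.5 Å; ties break lexicographically and are logged.  A
six-monomer structure is split into two trimers by exhaustively scoring
all ten 3+3 partitions on intra-group monomer–monomer contacts — cheap,
deterministic, and independent of any symmetry assumption.

The inter-chromophore distance table reports, per assembly level and pair
class, the minimum centre–centre distance over every chromophore pair of
that class present at the level (within one monomer / one trimer / the
hexamer).  Pairs within the same monomer therefore keep contributing at
higher levels, which is what makes the table monotone non-increasing down
the levels — an invariant asserted in the tests.  "Inter-site" classes
(two chromophores of the same attachment class) have no pair inside a
single monomer; such cells, and any distance beyond the 51 Å reporting
cap, are rendered `>51.0`.  A class with no chromophore at all is
reported absent instead.

The default distance convention is the unweighted centroid of the
conjugated system (rings B–D plus the BC/CD methines), which corresponds
to the chromophore's electronic centre better than an all-atom centroid
that would be skewed by the propionates and ring A.  `all_atoms` and
`ring_C` modes are provided for sensitivity runs, since published
distance tables rarely state their convention.

## Surface area, burial and solvent content

SASA uses Shrake–Rupley-style sphere sampling with a deterministic
golden-spiral point set (default 960 points), Bondi-type radii
(C 1.70, N 1.55, O 1.52, S 1.80 Å), and a 1.4 Å probe; unknown elements
fall back to a configurable default radius with a warning.  The single-
sphere case is exact by construction and the two-overlapping-spheres case
matches the closed-form cap area to ≤ 1 %; doubling the point count moves
a 100-atom total by < 0.5 %.  Buried area is the ΔASA identity
SASA(A)+SASA(B)−SASA(A∪B), symmetric and non-negative by construction.
Reported buried areas depend on the radius/sampling convention at the
few-percent level; comparisons across programs should expect that.

Solvent content follows Matthews: `V_M = V_cell/(Z·M_asu)` with the cell
volume from the general triclinic formula and Z the number of general
positions of the space group; solvent fraction = `1 − 1.230/V_M` with the
conventional 1.230 Å³/Da protein constant.  The ASU mass sums average
residue masses plus one water per chain plus bound chromophores
(586.68 Da per PCB) and excludes solvent waters.  `V_M ≤ 1.230` is
reported but flagged non-physical.

## Contacts

With no hydrogens in a typical ~2.3 Å structure, hydrogen bonds use the
heavy-atom criterion only: chromophore N/O/S to protein N/O/S within
3.5 Å, classified main-chain/side-chain by the partner atom.  The single
covalent pair (attachment cysteine SG to the ring-A substituent carbon)
is excluded from every contact list; the cysteine's other atoms remain
eligible, since excluding the whole residue would also hide its genuine
backbone hydrogen bonds.  Hydrophobic contacts pair apolar carbons, with
per-residue-type apolar lists shipped as data (a static approximation to
"carbon with no bonded N/O"); the binding pocket is the union of residues
within 4.5 Å of any chromophore atom, annotated hbond/hydrophobic/both/
proximal.  All cutoffs are configuration keys.

## Substitution analysis

A column of the alignment yields a substitution record when at least 90 %
of the non-query, non-gap residues agree on one residue and the query
differs; positions are reported in ungapped query numbering (1-based) so
they can be compared directly with author residue numbers.  The 0.9
threshold operationalises "invariant position" without being brittle to
a single divergent homolog.  Structural mapping verifies that the model
residue at the mapped position *is* the query residue and raises a hard
error otherwise — numbering drift between an alignment and a deposited
model is a silent-corruption hazard worth a crash.  Missing residues
(disordered termini) flag the chain as unmapped.

Compensatory pairs are substitution pairs whose side-chain heavy atoms
approach within 6 Å across any chain copies in the same or a contacting
monomer.  Evidence labels, in priority order: `gained_hbond` when the two
substituted side chains share a polar heavy-atom pair ≤ 3.5 Å;
`volume_complementary` when the summed residue-volume change (Zamyatnin
mean residue volumes) lies within ±40 Å³ of zero; otherwise
`proximity_only`.  Note the published three-way grouping in which a
valine gain (~ +51 Å³) is spread over two neighbouring conservative
swaps: each of its pairwise nets exceeds the ±40 Å³ window, so those
pairs carry `proximity_only` while the adjacency itself is still
detected.  The window is a documented heuristic, not a fitted constant.

One caveat the fixtures surface explicitly: published accounts are
internally inconsistent about whether the β-subunit Glu→Asp substitution
sits at position 87 or 187.  The packaged preset uses 87, which is the
position compatible with the tyrosine–aspartate hydrogen-bond geometry;
a `variant_b187` preset carries the alternative reading.

## Spectral deconvolution

The model is a constant baseline plus Gaussians in wavelength space (the
axis on which such fits are conventionally reported; a wavenumber-space
fit would be the physically flat choice but is deliberately not the
default).  Fitting is bounded trust-region least squares with an analytic
Jacobian, from 20 seeded starts whose centre initialisations come from
the negative minima of a Savitzky–Golay second derivative, ranked by
depth and pruned of wiggles shallower than 5 % of the deepest minimum;
later starts jitter centres (σ = 3 % of the window) and widths.  The
best-RSS solution wins, so the returned RSS is a non-increasing function
of the restart count.

Automatic component-count selection fits each n in a configured range
(default 1–4) and minimises the Bayesian information criterion.  BIC was
chosen over small-sample-corrected AIC after simulation at the default
generator conditions (three bands at 578/607/626 nm, 0.5 % noise, 301 grid
points): AICc's ≈ 2-units-per-parameter penalty lets a spurious fourth
Gaussian win whenever it absorbs more than ~2 % of residual noise, which
happened in roughly 40 % of replicates, while BIC's log(n) penalty
selects the true count essentially always and is the consistent
criterion for order selection.  Both values are reported on every fit
and `criterion="aicc"` restores the alternative.

Component shifts between two fitted models are index-matched after
sorting by centre; negative means the first model is blue-shifted.  When
three heavily overlapping reference bands are fitted (centres within one
band width), the individual centres are identifiable only to about 1 nm
— the worked blue-shift example is therefore quoted at that precision.

## Synthetic fixtures: what they emulate, and what they do not

Every generator is a deterministic function of (parameters, seed) down to
output bytes.

- `make_tetrapyrrole` builds four ideal planar pyrrole pentagons
  (1.38 Å bonds) joined by methine carbons.  A rigid planar ring attached
  through a bridge has one rotational degree of freedom, which sets the
  single-bond torsion and the inter-ring-plane angle *together*: the
  planted torsion (0 or 180°) selects the coplanar base rotamer and the
  planted plane angle is applied as a tilt about the bridge bond, giving
  torsion = base ± angle.  Inconsistent angle/torsion requests are
  rejected rather than approximated.  Planted angles are recovered by the
  analysis to ≤ 1e-6° at zero noise and degrade smoothly with coordinate
  noise.
- `make_toy_assembly` plants conjugated-system centroids exactly.  The
  default layout (monomer-local centroid triangle 50.9/38.7/50.0 Å,
  3-fold symmetry, second trimer mirrored, twisted 7.28° and shifted
  24.55 Å) was solved once, by least squares over the layout parameters,
  so that the resulting hexamer reproduces the published closest-distance
  table; every cell lands within the printed precision except the hexamer
  inter-β82 minimum, which comes out 33.3 Å against the published 33.1 Å
  (a 0.2 Å residual of the layout fit).  Chain stubs carry only enough
  protein atoms to drive monomer pairing and trimer grouping.
- `make_alignment` produces invariant reference rows plus a query
  differing exactly at the planted positions; the packaged preset plants
  the twelve conserved-position substitutions (3 α + 9 β).
- `make_compensation_structure` places the twelve substituted residues in
  two chains so that the three published compensation groupings hold
  geometrically (2.9 Å Tyr–Asp hydrogen bond; Trp against the Ala void;
  Val between Ile and Leu), with every other substituted position
  isolated.
- `make_spectrum` samples a Gaussian sum plus seeded noise; the default
  components put the band maxima at 578/607/626 nm with widths 18/14/12
  and amplitudes 0.60/0.90/0.75 — plausible phycocyanin band shapes
  chosen once, since only the maxima are published.

What passing closure tests establish: the analysis code measures exactly
what was planted, under the stated conventions, at the stated noise.
What they do not establish: robustness to real crystallographic pathology
(alternate conformations beyond simple altlocs, disorder, chain breaks,
unusual ligand naming), to deviations of real pentagon geometry from
ideal, or to correlated spectral baselines.  Quantities that depend on
the full deposited coordinates — the exact non-hydrogen atom census, the
real per-copy angle spread, the absolute αβ interface area — can only be
reproduced after the user fetches the deposited entry and runs
`phycostruct reproduce` on it.

## Problem sizes and determinism

Defaults used by the test suite and acceptance script: 960 SASA sphere
points (240 where only identities are asserted), 20 fit restarts,
automatic selection over n = 1–4, and a 100-replicate spectral recovery
study at 0.5 % noise.  All stochastic stages take explicit seeds; the
pipeline echoes its effective configuration, and identical configs
produce identical summaries.
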