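# Methods

## Scope

`dualvs` implements the scoring and analysis layer of a dual-target
(GPER + Bcl-2) virtual screen. Docking itself is out of scope: the package
consumes docked poses (SDF/PDB) and binding energies (CSV) produced by an
external docking engine, and produces interaction fingerprints, similarity
values, point scores and a composite ranking.

## Interaction fingerprinting

A fingerprint is the set of typed interaction records between one ligand pose
and one receptor structure. Nine specific types are detected, plus a generic
contact channel:

| type | geometry (defaults, all cutoffs inclusive) |
| --- | --- |
| `hbond` | heavy donor–acceptor ≤ 3.5 Å; D–H…A angle ≥ 120° when an explicit hydrogen is present, distance-only otherwise |
| `pi_pi_stacked` | ring centroid–centroid ≤ 5.5 Å, interplanar angle ≤ 30° |
| `pi_pi_tshaped` | centroid–centroid ≤ 5.5 Å, interplanar angle in [60°, 90°] |
| `pi_alkyl` | ring centroid to apolar atom ≤ 5.0 Å (both directions) |
| `pi_cation` | ring centroid to cationic-group centroid ≤ 5.0 Å |
| `pi_anion` | ring centroid to anionic-group centroid ≤ 5.0 Å |
| `pi_sulfur` | ring centroid to S (Met SD, Cys SG, ligand S) ≤ 5.5 Å |
| `alkyl` | apolar atom–atom ≤ 4.5 Å |
| `halogen` | ligand Cl/Br/I to receptor O/N/S ≤ 4.5 Å |
| `generic_contact` | any heavy-atom pair ≤ 4.0 Å (one record per residue, minimum distance) |

Receptor feature assignment uses residue-template tables (donors/acceptors,
aromatic rings, charged groups, sulfur atoms, apolar atoms); ligand feature
assignment uses the RDKit topology when available and falls back to
element-based rules otherwise. Histidine can be treated as cationic with the
`his_cationic` flag.

Two deliberate choices:

- **Apolar atoms are non-aromatic carbons** whose bonded neighbours are only
  carbon or hydrogen (plus halogens). Aromatic carbons participate through the
  π channels only; counting ring carbons as alkyl partners would duplicate
  every π–π contact as a π–alkyl contact and make the two channels
  inseparable.
- **All thresholds are inclusive** (`<=`), so a pair exactly at a cutoff is
  detected; the synthetic generators place planted geometries strictly inside
  and decoys strictly outside, so the benchmark does not depend on boundary
  ties.

The accelerated path prefilters residues with a SciPy cKDTree using radius
`max_cutoff + 2 × 3.0 Å` (the ring-radius pad covers centroid-based types); it
is record-for-record identical to the brute-force path and this identity is
asserted in the benchmark.

## Binding-mode similarity

`%similarityBM = 100 × |test ∩ control| / |control|`, where both operands are
interacting-residue sets and the control set comes from fingerprinting a
reference ligand (e.g. Gossypol for Bcl-2). The worked example: the residues
shared by both designed leads overlap the 13-residue Gossypol control set in
7 residues, giving 100 × 7/13 = 53.85 %. A `count_ratio` interpretation
(`100 × |test| / |control|`, which can exceed 100) is available behind the
`similarity_interpretation` config switch; the control-fraction form is the
default because it is bounded and measures binding-mode reproduction rather
than contact count.

## Point scores and composite

- **Drug-likeness**: 10 points per property inside the target range, ranges
  inclusive: MW [200, 500], logP [2, 5], HBA [5, 10], HBD [2, 5]; 0–40 total.
- **Toxicological risk**: four endpoints (mutagenicity, teratogenicity,
  tumorigenicity, irritability), each scored high = 0, medium = 10,
  low = 20; 0–80 total.
- **Metabolism**: a single predisposition level penalised high = −20,
  medium = −15, low = −10.

Composite for a ligand over targets *T*:

```
score = Σ_{t∈T} ( |BE_t| + %similarityBM_t ) + lipinski + tox + metabolism
```

Ligand-level terms are counted once regardless of the number of targets. The
composite is intentionally unscaled (energies in kcal/mol magnitude, the other
terms in points); an optional `normalize` switch min-max rescales the |BE|
terms to [0, 100] per target before summation, off by default. Ranking sorts
by composite descending with ties broken by ligand id, so it is a pure
function of the input set.

Missing annotations do not drop a ligand: the affected component scores at its
worst value (0 points, −20 penalty, |BE| = 0) and the ligand is flagged in the
`flags` column, keeping the ranking total over the library.

## Compound enumeration and mass checks

`enumerate_amide_products` condenses each carboxylic acid site of a scaffold
with each nucleophile (amines and sulfonamides) by explicit bond editing
(N gains the acyl bond, the hydroxyl oxygen leaves as water), so elemental
formulas are conserved by construction: product = acid + nucleophile − H₂O.
Monoisotopic masses are sums of most-abundant-isotope masses over the
elemental formula. The lead amide of the G1-PABA scaffold with
4-methylbenzenesulfonamide has formula C27H23BrN2O5S and monoisotopic mass
566.0511 Da; note this formula's [M−H]⁻ is consistent with the reported HRMS
value even where a transcribed formula elsewhere differs by one hydrogen.

## Synthetic ground truth

Because real docked complexes have no exact interaction ground truth, the
benchmark inputs are generated:

- **Pocket fixtures** (`make_pocket_fixture`): each planted interaction or
  decoy occupies its own direction on a Fibonacci sphere (probe radius 30 Å,
  widened automatically until all units are ≥ 8.5 Å apart), with a receptor
  fragment (SER/PHE/LEU/LYS/GLU/MET templates) and a minimal ligand probe
  (formaldehyde, benzene, methane, Cl/HCl). Planted geometries sit ≥ 0.2 Å /
  10° inside their thresholds; decoys sit 0.5 Å outside the distance cutoff or
  in the angle gap of the angle-gated types. All randomness flows from
  `numpy.random.default_rng(seed)`, coordinates are rounded to PDB precision
  (3 decimals), and the same seed reproduces byte-identical files.
- **Screening libraries** (`make_ligand_library`): property, risk, metabolism
  and energy tables with controlled in-range fractions and level mixtures,
  fingerprints drawn as subsets of per-target control sets, and an
  **expected-score oracle** computed inside the generator from the sampled
  values with the point rules restated independently of the scoring module.
  The oracle comparison is exact (no tolerance): generator and scorer use the
  same summation order, so agreement is bit-level.

Benchmark sizes (100 pockets × 20 planted + 20 decoys; 500-ligand library)
are the package's own regression-test choices, large enough to exercise every
type and decoy kind many times while keeping the suite under a minute.

## Numerical and determinism choices

- Detection uses double precision throughout; no tolerances are added to the
  cutoffs themselves.
- Fingerprints are invariant under rigid motion of the complex up to
  floating-point round-off; the determinism test applies 20 random
  rotations + translations and requires zero changes in the typed pairs.
- All CSV output is written with `float_format="%.4f"`, and pipeline reruns
  on identical inputs are byte-identical.
- The benchmark metric is deduplicated (residue, type) pairs with
  `generic_contact` excluded: generic contacts are a completeness channel,
  not a claim about interaction type, and one planted unit can legitimately
  produce several equivalent atom-level records (e.g. a ring with six
  carbons).

## Limitations

- Detectors are template-based for the 20 standard residues; modified
  residues, cofactors and metals fall back to element-based rules or the
  generic channel.
- Hydrogen-bond detection is distance-only when the structure lacks explicit
  hydrogens, which overcounts weak donors.
- The synthetic pockets validate detector geometry, not docking realism; they
  make no claim about pose quality or energy accuracy.
- The composite score is a transparent re-ranking heuristic, not a calibrated
  affinity model; weights are fixed by the point rules above.
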