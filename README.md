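# dualvs

Dual-target virtual-screening toolkit for GPER + Bcl-2 ligand design: typed
protein–ligand interaction fingerprints, binding-mode similarity, point-based
drug-likeness/toxicity/metabolism scoring, composite ranking, and amide-library
enumeration with exact-mass verification.

The package covers the computational core of a dual-target screen in which a
tetrahydroquinoline carboxylic acid (the G1-PABA scaffold) is decorated by
amide coupling with sulfonamides, docked against GPER and Bcl-2, and ranked by
a composite of binding energy, binding-mode similarity to control ligands, and
ligand-level point scores.

## Library layout

| module | contents |
| --- | --- |
| `dualvs.chem` | formula arithmetic, monoisotopic masses, RDKit property profiles, amide-coupling enumeration |
| `dualvs.structio` | receptor PDB and pose SDF/PDB reading, binding-energy tables |
| `dualvs.interactions` | geometric detectors for 9 typed interactions + generic contacts; brute-force and KD-tree-accelerated paths |
| `dualvs.scoring` | %similarityBM, Lipinski/toxicity/metabolism point rules, composite score, ranking |
| `dualvs.synthetic` | ground-truth pocket fixtures and screening-library generators used by the test suite and benchmarks |
| `dualvs.pipeline` | YAML-configured end-to-end screen with deterministic CSV/JSON outputs |
| `dualvs.cli` | `dualvs` command-line entry point |

## Worked example

Compound design and mass verification (the lead amide of G1-PABA with
4-methylbenzenesulfonamide):

```text
$ dualvs mass C27H23BrN2O5S
C27H23BrN2O5S   566.0511
```

```python
>>> from dualvs.chem import enumerate_amide_products, monoisotopic_mass
>>> from dualvs.reference import g1_paba, sulfonamide_nucleophiles
>>> products = enumerate_amide_products(g1_paba(), sulfonamide_nucleophiles())
>>> [(p.id, p.formula().hill(), round(monoisotopic_mass(p.formula()), 4)) for p in products]
[('G1-PABA+4-methylbenzenesulfonamide', 'C27H23BrN2O5S', 566.0511),
 ('G1-PABA+4-chlorobenzenesulfonamide', 'C26H20BrClN2O5S', 585.9965)]
```

Binding-mode similarity of the leads against the Gossypol control set on
Bcl-2 (7 shared residues out of 13 control residues):

```python
>>> from dualvs.reference import GOSSYPOL_BCL2_RESIDUES, LEADS_BCL2_RESIDUES
>>> from dualvs.scoring import similarity_bm
>>> round(similarity_bm(LEADS_BCL2_RESIDUES, GOSSYPOL_BCL2_RESIDUES), 2)
53.85
```

Full screen from files (`dualvs score --config run.yaml`): the config names
per-target receptor PDBs, control poses and docked-pose SDFs, plus shared
energy/property/risk/metabolism CSVs; outputs are `scores.csv`, `ranked.csv`,
per-pose fingerprint JSONs and a `manifest.json` with library versions. Reruns
are byte-identical.

## Command-line interface

```text
dualvs mass FORMULA [--adduct [M+H]+|[M-H]-]   exact masses
dualvs fingerprint --receptor R --poses P -o D typed fingerprints + contact tables
dualvs score --config run.yaml                 full pipeline
dualvs rank --scores scores.csv -o out.csv     deterministic re-ranking
dualvs synth pocket|library ...                synthetic test inputs
```

See `docs/methods.md` for the scoring model, detector geometry and the
design of the synthetic ground-truth generators.
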