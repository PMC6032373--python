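# dotrna

Analysis of **disorder-to-order transition (DOT) regions** in protein–RNA
complexes: intrinsically disordered protein segments that are unresolved in
the free protein's crystal structure but fold and become resolved when bound
to RNA. The package is aimed at structural bioinformaticians studying how
disordered regions recognise RNA — which residue types fold upon binding,
what they contact, how exposed they are, and how favourable the resulting
amino-acid–nucleotide interactions are.

## What it computes

**DOT detection.** Given a free-protein structure and an RNA-bound complex of
the same sequence (paired at ≥ 99 % identity), a residue is a DOT residue when
it appears in the free structure's REMARK 465 missing-residue list but carries
coordinates in the complex. Maximal runs of ≥ 3 consecutive DOT residues form
DOT regions. Residues that are merely mobile but have coordinates are never
counted as disordered.

**Interface statistics.** A protein residue contacts a nucleotide when the
minimum heavy-atom distance is within a cutoff (3.5 Å and 6 Å by default).
With per-type counts

- `N_ip` — residues of type *i* in the protein, `N_p` total residues,
- `N_id` — residues of type *i* in DOT regions,
- `N_ib` — residues of type *i* contacting RNA anywhere,
- `N_ibd` — residues of type *i* contacting RNA within DOT regions,

the package reports the binding frequency in DOT regions `N_ibd / N_id`, the
fraction of binders that are in DOT regions `N_ibd / N_ib`, and the binding
propensity

```
Propensity(i) = (N_ibd / N_id) / (N_ip / N_p)
```

(1 = no enrichment over the protein's composition). Standard errors come
from bootstrap resampling of whole complexes (1000 samples by default).
An exact binomial tail tests depletion (e.g. zero Met or Trp at the DOT
interface against a background fraction). Contacts are cross-tabulated
against protein secondary structure (DSSP 3-state: helix H/G/I, sheet E/B,
other) and RNA pairing state from dot-bracket annotation (unpaired `.`,
base-paired `()`, pseudoknot `[]{}<>`).

**Accessibility and energy.** Per-residue solvent-accessible surface area by
Shrake–Rupley (probe 1.4 Å, deterministic 960-point sphere), reported
relative to per-type extended-reference maxima (RASA, %). Interface
amino-acid–nucleotide pair energies use a 12-6 Lennard-Jones plus Coulomb
sum over heavy-atom pairs,

```
E = Σ_ij [ A_ij/r_ij^12 − B_ij/r_ij^6 + k·q_i·q_j/(ε·r_ij) ]
A_ij = ε*_ij (R*_ij)^12,  B_ij = 2 ε*_ij (R*_ij)^6,
R*_ij = R*_i + R*_j,      ε*_ij = √(ε*_i ε*_j)
```

with k = 332.0637 kcal·Å/(mol·e²) and an editable AMBER-style parameter
table, averaged per amino-acid × nucleotide cell and stratified DOT vs
non-DOT.

**Synthetic fixtures.** A first-class generator builds free/bound PDB pairs
with ideal-geometry backbones, controlled missing-residue runs, contacts
pinned at requested distances (± 0.05 Å), balanced dot-bracket strings, and
count scenarios whose pooled propensities match analytic targets — every
stage of the pipeline is testable without any database download.

## Worked example

```python
from dotrna import (FixtureSpec, generate_pair, read_structure, build_mapping,
                    StructurePair, detect, find_contacts, build_count_table,
                    propensity, depletion_test)

spec = FixtureSpec(n_residues=30, missing_free=[(10, 6)],
                   contact_plan=[(12, 0, 3.0), (14, 1, 3.2)], seed=7)
free_text, bound_text, _ = generate_pair(spec)
free, bound = read_structure(free_text), read_structure(bound_text)
pair = StructurePair(free, bound, build_mapping(free, bound))
regions = detect(pair)
dot = {k for r in regions for k in r.residues}
contacts = find_contacts(bound, 3.5, dot)
```

prints, for this seed:

```
DOT region: chain A residues 10-15 (length 6)
contact: A:12:TRP -- R:1:G  d = 3.00 A  in_dot=True
contact: A:14:ALA -- R:2:G  d = 3.20 A  in_dot=True
propensity: {'ALA': 30.0, 'TRP': 15.0}
P(0 Met among 96 interface residues | p=1.5%) = 0.234
```

The six residues missing in the free form but present in the complex are
recovered as one DOT region; the two planned contacts appear at their pinned
distances; with only two binding residues in a 30-residue chain the Trp and
Ala propensities are far above 1, as expected at this tiny scale. The last
line is the depletion test: observing zero methionines among 96 interface
residues is not significant at a 1.5 % background (p ≈ 0.23).

## Command line

```
dotrna simulate --n 5 --seed 1 --outdir fixtures   # synthetic fixture pairs
dotrna detect   --manifest fixtures/manifest.tsv   # DOT regions only
dotrna analyze  --manifest fixtures/manifest.tsv   # full report bundle
dotrna energy   --manifest fixtures/manifest.tsv   # pair-energy tables
```

The manifest is a TSV with columns `complex_id`, `free_pdb`, `bound_pdb`,
`class` (NR/RB) and optional `dotbracket` / `dssp` paths. All tables are TSV;
a JSON run log records the configuration and per-complex outcomes.

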