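# Methods

## DOT detection model

A disorder-to-order transition is operationalised purely from crystallographic
missing-residue bookkeeping: a residue is *disordered* in a structure iff it
is listed in that structure's REMARK 465 block (present in the construct,
unresolved in the density), and a DOT residue is one disordered in the free
protein and resolved in the RNA-bound complex. This is deliberately
conservative — residues with coordinates but high mobility are never called
disordered, so the method under-reports disorder where crystallisation
stabilised the chain.

Free and bound structures are paired by residue correspondence: identical
author numbering when the chains agree, otherwise global pairwise alignment
of the full sequences (observed + missing residues, in numbering order).
Either route must reach ≥ 99 % identity over aligned positions — below that
the two structures are not accepted as the same protein. Multi-chain
ambiguities are resolved by an explicit chain-pairing argument.

Regions are maximal runs of ≥ 3 consecutive DOT residues. *Consecutive*
means author numbering advances by 0 or 1 within one chain: an
insertion-coded pair (52, 52A) is consecutive, while a numbering jump
(30 → 41) breaks a run even when the gap is not annotated as missing,
because adjacency cannot be asserted there. Region-length histograms default
to bins 3–10 / 11–20 / 21–50 / > 50 (configurable).

## Contacts and interface statistics

A residue–nucleotide pair is a contact when the minimum distance over heavy
(non-hydrogen) atom pairs is ≤ the cutoff; the boundary is closed, which must
be fixed somewhere for reproducibility. Cutoffs 3.5 Å and 6 Å are the two
conventions of the interface literature; both are computed by default.
Hydrogens are excluded because most crystal structures lack them.

Per-type counts (N_ip, N_id, N_ib, N_ibd; see README) pool over complexes
before any ratio is formed. The three statistics are ratios of these pooled
counts; types with a zero denominator are reported as undefined (NaN), never
as 0. Bootstrap standard errors resample whole complexes with replacement —
the complex, not the residue, is the sampling unit — with 1000 samples by
default; sampling uses `numpy.random.default_rng`, so a fixed seed gives
bit-identical errors. The depletion test is an exact binomial tail
P(X ≤ observed) at the supplied background fraction; the background (e.g.
1.5 % Met, 2.7 % Trp) is an input, since background composition estimates
vary by source.

On the RNA side, a nucleotide is counted once per table (distinct-nucleotide
convention) regardless of how many residues it touches; a nucleotide
contacting both a DOT and a non-DOT residue therefore contributes once to
N_prot and once to N_idt.

Reported percentages use round-half-up at the table's decimal convention.

## Secondary structure

Protein: DSSP letters map to three states (H/G/I → helix, E/B → sheet,
everything else → other, matching the usual coil/turn/bend grouping). When
no DSSP output is supplied, an internal fallback assigns states from
backbone dihedral basins — helix φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°];
extended φ ∈ [−180°, −60°], ψ ∈ [90°, 180°] — kept only over runs of ≥ 4
consecutive residues. This is *not* a hydrogen-bond (Kabsch–Sander)
assignment; it exists for ideal-geometry synthetic structures where the
basins are unambiguous, and terminal residues with a single defined angle
inherit the basin of that angle.

RNA: dot-bracket strings are parsed with per-family bracket balancing.
`.` is unpaired, `()` nested pairs, `[] {} <>` pseudoknot families. The
three classes partition all positions.

## Solvent accessibility

Shrake–Rupley with a 1.4 Å probe and a deterministic Fibonacci sphere of
960 points per atom (doubling the point count changes totals by < 0.5 % on
fixtures). Radii are a NACCESS-compatible heavy-atom set shipped as data
(C 1.87, N 1.65, O 1.40, S 1.85, P 1.90 Å). Per-atom areas sum into
residues, so per-residue SASA partitions the structure total exactly.
Relative accessibility divides by per-type extended-reference maxima
(theoretical Ala-X-Ala-style values, Tien et al. 2013), shipped as an
editable table; values above 100 % are possible for extended conformations.
The whole-protein reference is computed on the protein component alone by
default (the RNA would otherwise occlude the interface); computing it on the
full complex is exposed as an option. RASA is reported on the percent scale
throughout; a per-complex share normalisation (each DOT residue's RASA over
the sum across the complex's DOT residues) is available as an alternative
output column rather than the primary quantity, since percent-scale values
are the ones comparable across complexes.

## Interaction energy

12-6 Lennard-Jones in the A/B form (A = ε\*R\*¹², B = 2ε\*R\*⁶, minimum
exactly −ε\*_ij at r = R\*_ij) plus Coulomb k·q_i·q_j/(ε·r) with
k = 332.0637 kcal·Å/(mol·e²). Combination rules: R\*_ij = R\*_i + R\*_j,
ε\*_ij = √(ε\*_i ε\*_j). The dielectric defaults to 1.0 with a
distance-dependent option (ε = r). Atom-pair sums stop at a 10 Å evaluation
shell, where both terms are negligible at this energy scale (configurable).
Pair energies are means per residue–nucleotide pair (not per atom pair),
stratified by whether the protein residue lies in a DOT region; empty cells
report 0.00 with a count of 0.

Parameters are an AMBER-style table (R\*, ε\*, partial charge per atom name,
united-atom element fallbacks) shipped as an editable data file — they are
configuration, not constants of the method. Atoms resolved through an
element fallback get charge 0 with a warning; strict mode turns that into an
error.

## Synthetic data: what it emulates and what it does not

The generator emulates the *bookkeeping and geometry* the pipeline consumes:
REMARK 465 blocks with controlled runs, ideal-geometry backbones (helix
φ = −57°, ψ = −47°; extended φ = −120°, ψ = +120°; N, CA, C, O + CB), reduced
three-atom nucleotides (P, C1′, glycosidic N), contacts pinned by translating
nucleotides along a locally outward direction until the minimum heavy-atom
distance matches the request within 0.05 Å, and balanced dot-bracket strings
with exact class counts. Ground-truth contact sets are measured by a direct
all-pairs distance scan over the generated coordinates, independent of the
KD-tree path used by the analysis, and include any incidental contacts the
geometry creates.

Count scenarios fix, for each residue type, the total number of binding DOT
residues across the dataset at its expectation (round(rate × n)) and assign
them to randomly chosen complexes. Pooled propensities therefore equal their
targets up to that rounding, while bootstrap resampling still sees
between-complex variability; with independent per-residue draws at
realistic dataset sizes the sampling noise would swamp the targets, which
would test the random number generator rather than the statistics.

Passing on these fixtures demonstrates that the bookkeeping, geometry and
statistics are computed correctly. It does not demonstrate robustness to
real-data pathologies — alternate conformations beyond simple altlocs,
chain breaks with heteroatom inserts, non-ideal secondary structure, or
physically realistic side-chain packing — and the energy fixtures use
reduced atom sets with representative rather than complete force-field
parameters.

## Numerical choices

- Contact boundary closed (d ≤ cutoff is a contact); ties in altloc
  occupancy resolve to the first conformer in file order.
- Percentages and fold differences round half-up at the reporting step only;
  internal arithmetic is double precision.
- SASA point sets, bootstrap draws and generator draws all derive from
  explicit seeds; the pipeline's run log records the root seed, and report
  bundles are byte-identical across reruns with the same manifest and seed.
- Problem sizes in the validation runs — 100 random fixtures for the contact
  and DOT-recovery oracles, 200 complexes for propensity recovery, 1000
  bootstrap samples — keep every oracle comparison exhaustive at desk scale.
- Degenerate inputs fail loudly: empty structures, mixed polymer chains,
  unbalanced dot-brackets, zero interatomic distances and missing parameters
  raise errors naming the offending record.

## Known limitations

- First NMR model only; mmCIF is not parsed; ligand/ion chemistry ignored.
- The fallback secondary-structure assigner is dihedral-based and should not
  be used on experimental structures when DSSP output is available.
- Disorder visible only as elevated B-factors or partial occupancy is
  invisible to the REMARK 465 criterion.
- Energies are single-point interaction scores — no minimisation, solvation,
  or entropic terms — and are only as good as the parameter table supplied.
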