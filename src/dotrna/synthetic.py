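"""Synthetic free/bound structure fixtures with known ground truth.

Generates paired PDB texts (a free protein with controlled REMARK 465
missing-residue runs and the same protein bound to a small RNA chain),
dot-bracket annotations, and count scenarios with analytically known
binding propensities, so every pipeline stage can be tested without any
database download.

Protein chains use ideal-geometry backbones (N, CA, C, O + CB) built from
internal coordinates with helical (phi=-57, psi=-47) or extended strand
(phi=-120, psi=+120) dihedrals. RNA chains carry a reduced three-atom
nucleotide (P, C1', and the glycosidic base nitrogen N9/N1). Contacts are
realised by translating nucleotides until the minimum heavy-atom distance
to the target residue matches the requested value within 0.05 Å; the
ground-truth record then lists the contact sets actually realised, measured
by a direct all-pairs distance scan independent of the analysis code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .structure_io import (AA1_TO_3, AA3_TO_1, AMINO_ACIDS, NUCLEOTIDES,
                           AtomRecord, ResidueKey, Structure, to_pdb)

PROTEIN_CHAIN = "A"
RNA_CHAIN = "R"
STERIC_FLOOR = 2.0  # Å; contact targets below this are rejected

# ideal backbone internal coordinates (Å, degrees)
_BOND_N_CA, _BOND_CA_C, _BOND_C_N = 1.458, 1.525, 1.329
_BOND_C_O, _BOND_CA_CB = 1.231, 1.521
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7
_ANG_CA_C_O, _ANG_N_CA_CB = 120.5, 110.4
_DIHEDRALS = {"H": (-57.0, -47.0), "E": (-120.0, 120.0)}


class InfeasibleFixture(ValueError):
    """The fixture specification cannot be realised geometrically."""


@dataclass
class FixtureSpec:
    """Declarative description of one free/bound fixture pair.

    ``missing_free``/``missing_bound`` are (start, length) runs of residues
    omitted from the ATOM records and listed in REMARK 465. ``contact_plan``
    entries (residue number, nucleotide index, minimum distance Å) pin one
    nucleotide at a controlled distance from one bound residue.
    """

    n_residues: int
    sequence: Optional[str] = None              # 1-letter; drawn if None
    composition: Optional[Mapping[str, float]] = None
    ss_plan: Optional[str] = None               # per-residue 'H'/'E'; default helix
    missing_free: Sequence[Tuple[int, int]] = field(default_factory=list)
    missing_bound: Sequence[Tuple[int, int]] = field(default_factory=list)
    contact_plan: Sequence[Tuple[int, int, float]] = field(default_factory=list)
    n_nucleotides: int = 4
    rna_sequence: Optional[str] = None
    dotbracket: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        for runs in (self.missing_free, self.missing_bound):
            spans = sorted((s, s + l - 1) for s, l in runs)
            for (s, e) in spans:
                if s < 1 or e > self.n_residues or e < s:
                    raise InfeasibleFixture(f"missing run {s}-{e} outside chain")
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise InfeasibleFixture("overlapping missing runs")
        bound_missing = self._expand(self.missing_bound)
        used_nt = set()
        for res, nt, d in self.contact_plan:
            if d <= STERIC_FLOOR:
                raise InfeasibleFixture(f"contact distance {d} below steric floor")
            if not 1 <= res <= self.n_residues or res in bound_missing:
                raise InfeasibleFixture(f"contact residue {res} absent from bound structure")
            if not 0 <= nt < self.n_nucleotides:
                raise InfeasibleFixture(f"nucleotide index {nt} out of range")
            if nt in used_nt:
                raise InfeasibleFixture(f"nucleotide {nt} targeted by two contacts")
            used_nt.add(nt)

    @staticmethod
    def _expand(runs: Sequence[Tuple[int, int]]) -> set:
        out = set()
        for s, l in runs:
            out.update(range(s, s + l))
        return out


# ---------------------------------------------------------------------------
# geometry

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates (angle b-c-d, torsion a-b-c-d)."""
    theta, chi = math.radians(angle_deg), math.radians(torsion_deg)
    w = c - b
    w /= np.linalg.norm(w)
    u = b - a
    n = np.cross(u, w)
    n /= np.linalg.norm(n)
    m = np.cross(n, w)
    d = (-bond * math.cos(theta)) * w \
        + (bond * math.sin(theta) * math.cos(chi)) * m \
        + (bond * math.sin(theta) * math.sin(chi)) * n
    return c + d


def build_backbone(sequence3: Sequence[str], ss_plan: str) -> Dict[int, List[Tuple[str, str, np.ndarray]]]:
    """Ideal-geometry backbone (+CB for non-Gly) for a 1..n protein chain.

    Returns per residue number a list of (atom name, element, coordinates).
    """
    n = len(sequence3)
    N = [np.zeros(3)]
    CA = [np.array([_BOND_N_CA, 0.0, 0.0])]
    ang = math.radians(_ANG_N_CA_C)
    C = [CA[0] + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n):
        phi, psi_prev = _DIHEDRALS[ss_plan[i]][0], _DIHEDRALS[ss_plan[i - 1]][1]
        Ni = _nerf(N[i - 1], CA[i - 1], C[i - 1], _BOND_C_N, _ANG_CA_C_N, psi_prev)
        CAi = _nerf(CA[i - 1], C[i - 1], Ni, _BOND_N_CA, _ANG_C_N_CA, 180.0)
        Ci = _nerf(C[i - 1], Ni, CAi, _BOND_CA_C, _ANG_N_CA_C, phi)
        N.append(Ni), CA.append(CAi), C.append(Ci)
    out: Dict[int, List[Tuple[str, str, np.ndarray]]] = {}
    for i in range(n):
        psi = _DIHEDRALS[ss_plan[i]][1]
        atoms = [("N", "N", N[i]), ("CA", "C", CA[i]), ("C", "C", C[i])]
        # carbonyl O anti to the next amide N; CB from the standard improper
        atoms.append(("O", "O", _nerf(N[i], CA[i], C[i], _BOND_C_O, _ANG_CA_C_O, psi + 180.0)))
        if sequence3[i] != "GLY":
            atoms.append(("CB", "C", _nerf(C[i], N[i], CA[i], _BOND_CA_CB,
                                           _ANG_N_CA_CB, 122.5)))
        out[i + 1] = atoms
    return out


_BASE_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}


def _nucleotide_atoms(nt: str, anchor: np.ndarray, u: np.ndarray,
                      v: np.ndarray) -> List[Tuple[str, str, np.ndarray]]:
    """Reduced nucleotide extending outward along u from its base nitrogen."""
    return [(_BASE_N[nt], "N", anchor),
            ("C1'", "C", anchor + 1.5 * u + 0.5 * v),
            ("P", "P", anchor + 3.0 * u - 0.5 * v)]


# ---------------------------------------------------------------------------
# fixture generation

def _draw_sequence(spec: FixtureSpec, rng: np.random.Generator) -> List[str]:
    if spec.sequence is not None:
        if len(spec.sequence) != spec.n_residues:
            raise InfeasibleFixture("explicit sequence length mismatch")
        return [AA1_TO_3[c] for c in spec.sequence.upper()]
    if spec.composition:
        names = sorted(spec.composition)
        probs = np.array([spec.composition[k] for k in names], dtype=float)
        probs /= probs.sum()
        picks = rng.choice(len(names), size=spec.n_residues, p=probs)
        return [names[i] if len(names[i]) == 3 else AA1_TO_3[names[i]] for i in picks]
    picks = rng.integers(0, len(AMINO_ACIDS), size=spec.n_residues)
    return [AMINO_ACIDS[i] for i in picks]


def _min_distances(prot_xyz: Dict[int, np.ndarray],
                   nt_xyz: np.ndarray) -> Dict[int, float]:
    """Minimum distance from each protein residue's atoms to one nucleotide."""
    out = {}
    for res, xyz in prot_xyz.items():
        diff = xyz[:, None, :] - nt_xyz[None, :, :]
        out[res] = float(np.sqrt((diff ** 2).sum(axis=2)).min())
    return out


def _segment_ground_truth(dot_nums: List[int], min_len: int = 3) -> List[Tuple[int, int]]:
    """Independent run scan over sorted residue numbers -> (start, end) regions."""
    regions = []
    run: List[int] = []
    for n in sorted(dot_nums):
        if run and n == run[-1] + 1:
            run.append(n)
        else:
            if len(run) >= min_len:
                regions.append((run[0], run[-1]))
            run = [n]
    if len(run) >= min_len:
        regions.append((run[0], run[-1]))
    return regions


def generate_pair(spec: FixtureSpec) -> Tuple[str, str, dict]:
    """Build (free PDB text, bound PDB text, ground-truth record).

    The ground truth lists the expected DOT regions, the realised contact
    sets at 3.5 and 6 Å (from a direct all-pairs distance scan over the
    generated coordinates), and the per-type counts they imply.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    seq3 = _draw_sequence(spec, rng)
    ss_plan = spec.ss_plan or "H" * spec.n_residues
    if len(ss_plan) != spec.n_residues or set(ss_plan) - set("HE"):
        raise InfeasibleFixture("ss_plan must be one 'H'/'E' letter per residue")
    backbone = build_backbone(seq3, ss_plan)

    missing_free = spec._expand(spec.missing_free)
    missing_bound = spec._expand(spec.missing_bound)

    # bound-side protein coordinates (per residue heavy-atom arrays)
    prot_xyz = {res: np.array([p for (_, _, p) in atoms])
                for res, atoms in backbone.items() if res not in missing_bound}
    centroid = np.concatenate(list(prot_xyz.values())).mean(axis=0)

    rna_seq = (spec.rna_sequence.upper() if spec.rna_sequence
               else "".join(NUCLEOTIDES[i] for i in
                            rng.integers(0, 4, size=spec.n_nucleotides)))
    if len(rna_seq) != spec.n_nucleotides:
        raise InfeasibleFixture("rna_sequence length mismatch")

    # nucleotide placement: contacted ones pinned near their residue,
    # the rest parked far from the protein and from each other
    nt_positions: Dict[int, List[Tuple[str, str, np.ndarray]]] = {}
    planned = {nt: (res, d) for res, nt, d in spec.contact_plan}
    for j in range(spec.n_nucleotides):
        if j in planned:
            res, d = planned[j]
            atoms = prot_xyz[res]
            ref = atoms[-1]  # CB (or O for Gly): outermost of the reduced set
            # outward = away from the local body of the chain, not the global
            # centroid (which lies on the helix axis and would drag the
            # nucleotide across neighbouring turns)
            local = np.concatenate([prot_xyz[r] for r in prot_xyz
                                    if abs(r - res) <= 5]).mean(axis=0)
            u = ref - local
            # project out the local chain tangent so the nucleotide sits over
            # this residue rather than drifting toward a neighbour
            neighbours = [r for r in (res - 1, res + 1) if r in prot_xyz]
            if len(neighbours) == 2:
                t = prot_xyz[neighbours[1]][0] - prot_xyz[neighbours[0]][0]
                t /= np.linalg.norm(t)
                u = u - (u @ t) * t
            norm = np.linalg.norm(u)
            u = u / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
            v = np.cross(u, [0.0, 0.0, 1.0])
            if np.linalg.norm(v) < 1e-6:
                v = np.cross(u, [0.0, 1.0, 0.0])
            v /= np.linalg.norm(v)
            anchor = ref + d * u
            for _ in range(60):
                nt_atoms = _nucleotide_atoms(rna_seq[j], anchor, u, v)
                nt_xyz = np.array([p for (_, _, p) in nt_atoms])
                dists = _min_distances(prot_xyz, nt_xyz)
                if min(dists.values()) <= STERIC_FLOOR:
                    anchor = anchor + 0.5 * u  # back off a clash and retry
                    continue
                if abs(dists[res] - d) <= 0.02:
                    break
                anchor = anchor + (d - dists[res]) * u
            else:
                raise InfeasibleFixture(
                    f"could not realise contact to residue {res} at {d:.2f} Å")
            nt_positions[j] = nt_atoms
        else:
            far = centroid + np.array([25.0 * j, 200.0, 0.0])
            nt_positions[j] = _nucleotide_atoms(rna_seq[j], far,
                                                np.array([0.0, 1.0, 0.0]),
                                                np.array([1.0, 0.0, 0.0]))

    # assemble structures
    def protein_records(missing: set) -> Tuple[List[AtomRecord], List[ResidueKey]]:
        recs, miss = [], []
        for res in range(1, spec.n_residues + 1):
            key = ResidueKey(PROTEIN_CHAIN, res, "", seq3[res - 1])
            if res in missing:
                miss.append(key)
                continue
            for name, elem, p in backbone[res]:
                recs.append(AtomRecord(key, name, elem,
                                       round(p[0], 3), round(p[1], 3), round(p[2], 3)))
        return recs, miss

    free_atoms, free_missing_keys = protein_records(missing_free)
    bound_atoms, bound_missing_keys = protein_records(missing_bound)
    for j in range(spec.n_nucleotides):
        key = ResidueKey(RNA_CHAIN, j + 1, "", rna_seq[j])
        for name, elem, p in nt_positions[j]:
            bound_atoms.append(AtomRecord(key, name, elem,
                                          round(p[0], 3), round(p[1], 3), round(p[2], 3)))

    free = Structure(atoms=free_atoms, missing=free_missing_keys,
                     chain_kinds={PROTEIN_CHAIN: "protein"}, name="free")
    bound = Structure(atoms=bound_atoms, missing=bound_missing_keys,
                      chain_kinds={PROTEIN_CHAIN: "protein", RNA_CHAIN: "rna"},
                      name="bound")

    # ground truth: realised contacts by direct all-pairs scan (written
    # coordinate precision), DOT regions by an independent run scan
    rounded_prot = {res: np.round(xyz, 3) for res, xyz in prot_xyz.items()}
    contacts: Dict[str, List[Tuple[int, int, float]]] = {"3.5": [], "6.0": []}
    for j in range(spec.n_nucleotides):
        nt_xyz = np.round(np.array([p for (_, _, p) in nt_positions[j]]), 3)
        for res, dm in _min_distances(rounded_prot, nt_xyz).items():
            for cutoff in (3.5, 6.0):
                if dm <= cutoff:
                    contacts[f"{cutoff:.1f}"].append((res, j + 1, round(dm, 4)))
    for res, nt, d in spec.contact_plan:
        realised = {r: dd for r, n, dd in contacts["6.0"] if n == nt + 1}.get(res) \
            if d <= 6.0 else None
        if d <= 6.0 and (realised is None or abs(realised - d) > 0.05):
            raise InfeasibleFixture(
                f"contact ({res}, {nt}, {d}) not realised within 0.05 Å")

    dot_nums = sorted(missing_free - missing_bound)
    regions = _segment_ground_truth(dot_nums)
    dot_in_regions = [n for s, e in regions for n in range(s, e + 1)]

    counts: Dict[str, dict] = {}
    for cut, pairs in contacts.items():
        binders = {r for r, _, _ in pairs}
        counts[cut] = {
            "n_ib": _per_type(seq3, [r for r in range(1, spec.n_residues + 1)
                                     if r not in missing_bound and r in binders]),
            "n_ibd": _per_type(seq3, [r for r in dot_in_regions if r in binders]),
        }
    truth = {
        "sequence": "".join(AA3_TO_1[a] for a in seq3),
        "rna_sequence": rna_seq,
        "dot_residues": dot_in_regions,
        "dot_regions": [{"chain": PROTEIN_CHAIN, "start": s, "end": e,
                         "length": e - s + 1} for s, e in regions],
        "contacts": {c: sorted(v) for c, v in contacts.items()},
        "n_ip": _per_type(seq3, [r for r in range(1, spec.n_residues + 1)
                                 if r not in missing_bound]),
        "n_id": _per_type(seq3, dot_in_regions),
        "counts_by_cutoff": counts,
        "n_p": spec.n_residues - len(missing_bound),
        "dotbracket": spec.dotbracket,
    }
    return to_pdb(free), to_pdb(bound), truth


def _per_type(seq3: Sequence[str], residue_numbers: Sequence[int]) -> Dict[str, int]:
    out = {aa: 0 for aa in AMINO_ACIDS}
    for r in residue_numbers:
        out[seq3[r - 1]] += 1
    return out


# ---------------------------------------------------------------------------
# dot-bracket generator

def generate_dotbracket(length: int, paired_fraction: float,
                        pseudoknot_fraction: float, seed: int = 0,
                        ) -> Tuple[str, str]:
    """Random sequence + balanced annotation with requested class fractions.

    Exactly round(fraction * length) positions fall in each bracket class,
    decremented to the nearest even number (pairs come two positions at a
    time). Nested-pair positions use ``()``, pseudoknot positions ``[]``.
    """
    if not (0 <= paired_fraction <= 1 and 0 <= pseudoknot_fraction <= 1
            and paired_fraction + pseudoknot_fraction <= 1):
        raise ValueError("fractions must be in [0,1] and sum to at most 1")
    rng = np.random.default_rng(seed)
    n_bp = int(round(paired_fraction * length)) // 2 * 2
    n_pk = int(round(pseudoknot_fraction * length)) // 2 * 2
    order = rng.permutation(length)
    bp_pos = sorted(order[:n_bp])
    pk_pos = sorted(order[n_bp:n_bp + n_pk])
    ann = ["."] * length
    for i, p in enumerate(bp_pos):
        ann[p] = "(" if i < n_bp // 2 else ")"
    for i, p in enumerate(pk_pos):
        ann[p] = "[" if i < n_pk // 2 else "]"
    seq = "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=length))
    return seq, "".join(ann)


# ---------------------------------------------------------------------------
# count scenarios with known propensity

DOT_START, DOT_LEN, SCENARIO_PROTEIN_LEN = 11, 20, 40
CONTACT_DISTANCE = 3.0  # Å, safely inside the 3.5 Å cutoff


def generate_count_scenario(target_propensities: Mapping[str, float],
                            n_complexes: int, seed: int = 0,
                            ) -> Tuple[List[FixtureSpec], Dict[str, float]]:
    """Fixture manifest whose pooled binding propensities match the targets.

    Each complex is a 40-residue extended chain containing every amino-acid
    type exactly twice, with a 20-residue DOT segment (one residue of each
    type, shuffled) missing in the free form. For type i with target
    propensity t_i the binding rate of its DOT residue is t_i/20 (the
    composition fraction is exactly 1/20); the total number of binding
    complexes per type is fixed at its expectation, round(rate * n), and
    assigned to randomly chosen complexes, so the pooled propensity equals
    the target up to that rounding while bootstrap resampling still sees
    between-complex variability.

    Returns the fixture specs plus the analytic expected propensities.
    """
    targets = {aa: float(target_propensities.get(aa, 1.0)) for aa in AMINO_ACIDS}
    for aa, t in targets.items():
        if not (t > 0 and math.isfinite(t)):
            raise ValueError(f"target propensity for {aa} must be positive and finite")
        if t / len(AMINO_ACIDS) > 1:
            raise ValueError(f"target propensity {t} for {aa} implies binding rate > 1")
    rng = np.random.default_rng(seed)
    if n_complexes == 0:
        return [], {}

    binder_complexes: Dict[str, set] = {}
    expected: Dict[str, float] = {}
    for aa in AMINO_ACIDS:
        k = int(round(targets[aa] / len(AMINO_ACIDS) * n_complexes))
        k = min(k, n_complexes)
        binder_complexes[aa] = set(rng.choice(n_complexes, size=k, replace=False).tolist())
        expected[aa] = len(AMINO_ACIDS) * k / n_complexes

    specs: List[FixtureSpec] = []
    for c in range(n_complexes):
        dot_types = list(rng.permutation(AMINO_ACIDS))
        flank_types = list(rng.permutation(AMINO_ACIDS))
        seq3 = flank_types[:10] + dot_types + flank_types[10:]
        plan = []
        nt_idx = 0
        for aa in AMINO_ACIDS:
            if c in binder_complexes[aa]:
                res = DOT_START + dot_types.index(aa)
                plan.append((res, nt_idx, CONTACT_DISTANCE))
                nt_idx += 1
        specs.append(FixtureSpec(
            n_residues=SCENARIO_PROTEIN_LEN,
            sequence="".join(AA3_TO_1[a] for a in seq3),
            ss_plan="E" * SCENARIO_PROTEIN_LEN,
            missing_free=[(DOT_START, DOT_LEN)],
            contact_plan=plan,
            n_nucleotides=max(nt_idx, 1) + 1,
            seed=int(rng.integers(2 ** 31)),
        ))
    return specs, expected


# ---------------------------------------------------------------------------
# randomised fixtures for oracle tests

def random_fixture_spec(rng: np.random.Generator) -> FixtureSpec:
    """A random but valid fixture: random missing runs and contact plan."""
    n = int(rng.integers(30, 61))
    runs: List[Tuple[int, int]] = []
    pos = 1
    for _ in range(int(rng.integers(0, 4))):
        start = pos + int(rng.integers(0, 6))
        length = int(rng.integers(1, 9))
        if start + length - 1 > n:
            break
        runs.append((start, length))
        pos = start + length + 1 + int(rng.integers(0, 4))
    bound_runs: List[Tuple[int, int]] = []
    for s, l in runs:  # occasionally re-disorder part of a free-missing run
        if l >= 4 and rng.random() < 0.3:
            bound_runs.append((s + 1, 1))
    bound_missing = FixtureSpec._expand(bound_runs)
    candidates = [r for r in range(1, n + 1) if r not in bound_missing]
    plan = []
    for j in range(int(rng.integers(0, 4))):
        res = int(rng.choice(candidates))
        candidates = [r for r in candidates if abs(r - res) > 4]
        plan.append((res, j, float(rng.uniform(2.6, 7.0))))
        if not candidates:
            break
    ss = "".join(rng.choice(["H", "E"]) for _ in range(1))  # chain-wide
    return FixtureSpec(n_residues=n, ss_plan=ss * n,
                       missing_free=runs, missing_bound=bound_runs,
                       contact_plan=plan, n_nucleotides=max(len(plan), 1) + 1,
                       seed=int(rng.integers(2 ** 31)))
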