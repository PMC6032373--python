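"""Solvent accessibility and pairwise interaction energies.

Two independent per-residue features of the binding interface:

* solvent-accessible surface area by the Shrake–Rupley rolling-probe
  method (probe 1.4 Å, deterministic Fibonacci point sphere), expressed
  relative to a per-residue-type extended-reference maximum (RASA, percent);
* amino-acid–nucleotide interaction energy as a 12-6 Lennard-Jones plus
  Coulomb sum over heavy-atom pairs,

      E = sum_ij [ A_ij / r_ij^12  -  B_ij / r_ij^6  +  k q_i q_j / (eps r_ij) ]

  with A_ij = eps*_ij (R*_ij)^12, B_ij = 2 eps*_ij (R*_ij)^6, the Lorentz
  combination R*_ij = R*_i + R*_j, geometric-mean well depth
  eps*_ij = sqrt(eps*_i eps*_j) and k = 332.0637 kcal Å / (mol e²).

Force-field parameters (AMBER-style R*, eps*, partial charges) and the
reference-accessibility table ship as editable columnar data files.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .interface_stats import ContactRecord, round_half_up
from .structure_io import AMINO_ACIDS, NUCLEOTIDES, AtomRecord, ResidueKey, Structure

logger = logging.getLogger("dotrna")

COULOMB_CONSTANT = 332.0637  # kcal*Angstrom/(mol*e^2)
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SPHERE_POINTS = 960
DEFAULT_EVALUATION_SHELL = 10.0


def _read_data_table(fname: str) -> pd.DataFrame:
    with importlib.resources.files("dotrna.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# solvent accessibility (Shrake-Rupley)

def load_vdw_radii() -> Dict[str, float]:
    df = _read_data_table("vdw_radii.tsv")
    return dict(zip(df["element"], df["radius"]))


def load_reference_sasa() -> Dict[str, float]:
    df = _read_data_table("reference_sasa.tsv")
    return dict(zip(df["residue"], df["max_sasa"]))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors; deterministic."""
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SASARecord:
    key: ResidueKey
    absolute_sasa: float
    relative_sasa: Optional[float] = None  # percent of type reference


def compute_sasa(structure: Structure,
                 probe_radius: float = DEFAULT_PROBE_RADIUS,
                 n_points: int = DEFAULT_SPHERE_POINTS,
                 radii: Optional[Mapping[str, float]] = None,
                 keys: Optional[Iterable[ResidueKey]] = None,
                 ) -> Dict[ResidueKey, float]:
    """Per-residue absolute SASA (Å²) of the heavy atoms of a structure.

    Shrake–Rupley: each atom's solvent-extended sphere (r + probe) is
    sampled with a fixed Fibonacci point set; points inside any neighbour's
    extended sphere are buried. Atom areas sum into residues, so the sum of
    the returned values is the total SASA. ``keys`` restricts which chains'
    atoms exist at all (e.g. protein component only); occlusion is computed
    among the selected atoms.
    """
    radii = dict(radii) if radii is not None else load_vdw_radii()
    xyz, atoms = structure.coords(keys, heavy_only=True)
    if len(atoms) == 0:
        return {}
    try:
        ext = np.array([radii[a.element] for a in atoms]) + probe_radius
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {exc.args[0]!r}") from None

    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(xyz)
    max_reach = 2.0 * ext.max()
    out: Dict[ResidueKey, float] = {}
    for i, atom in enumerate(atoms):
        pts = xyz[i] + ext[i] * sphere
        neighbours = [j for j in tree.query_ball_point(xyz[i], ext[i] + ext.max())
                      if j != i and np.linalg.norm(xyz[j] - xyz[i]) < ext[i] + ext[j]]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j])
            exposed &= d2 > ext[j] ** 2
        area = 4.0 * math.pi * ext[i] ** 2 * exposed.sum() / n_points
        out[atom.key] = out.get(atom.key, 0.0) + area
    return out


def relative_sasa(absolute: Mapping[ResidueKey, float],
                  reference: Optional[Mapping[str, float]] = None,
                  ) -> Dict[ResidueKey, float]:
    """Percent relative accessibility: 100 * absolute / type reference maximum."""
    reference = dict(reference) if reference is not None else load_reference_sasa()
    out: Dict[ResidueKey, float] = {}
    for key, area in absolute.items():
        if key.res_name not in reference:
            raise ValueError(f"residue type {key.res_name} absent from reference table")
        out[key] = 100.0 * area / reference[key.res_name]
    return out


def rasa_comparison_table(rasa: Mapping[ResidueKey, float],
                          dot_residues: Set[ResidueKey],
                          decimals: int = 3) -> pd.DataFrame:
    """Mean RASA of each amino-acid type in DOT regions vs the whole protein.

    Columns ``rasa_dot``, ``rasa_protein``, ``fold_difference`` (DOT mean /
    protein mean, rounded half-up to 3 decimals). Types absent from the DOT
    set get NaN in the DOT columns.
    """
    rows = []
    for aa in AMINO_ACIDS:
        all_vals = [v for k, v in rasa.items() if k.res_name == aa]
        dot_vals = [v for k, v in rasa.items() if k.res_name == aa and k in dot_residues]
        mean_all = float(np.mean(all_vals)) if all_vals else float("nan")
        mean_dot = float(np.mean(dot_vals)) if dot_vals else float("nan")
        fold = (round_half_up(mean_dot / mean_all, decimals)
                if dot_vals and all_vals and mean_all > 0 else float("nan"))
        rows.append({"residue": aa, "rasa_dot": mean_dot,
                     "rasa_protein": mean_all, "fold_difference": fold})
    return pd.DataFrame(rows).set_index("residue")


def fold_difference(mean_dot: float, mean_protein: float, decimals: int = 3) -> float:
    """DOT-region mean RASA over whole-protein mean RASA, rounded half-up."""
    return round_half_up(mean_dot / mean_protein, decimals)


# ---------------------------------------------------------------------------
# energy parameters

@dataclass
class EnergyParams:
    """Per-atom-type Lennard-Jones parameters and partial charges.

    ``table`` maps an atom-type key (PDB atom name, or ``element:X``
    fallback) to (R* Å, eps* kcal/mol, charge e). Missing charges default to
    0 with a warning unless ``strict``.
    """

    table: Dict[str, Tuple[float, float, float]]
    dielectric: float = 1.0
    distance_dependent_dielectric: bool = False
    coulomb_constant: float = COULOMB_CONSTANT
    evaluation_shell: float = DEFAULT_EVALUATION_SHELL
    strict: bool = False

    @classmethod
    def default(cls, **kwargs) -> "EnergyParams":
        df = _read_data_table("energy_params.tsv")
        table = {row.atom_type: (float(row.rstar), float(row.epsstar), float(row.charge))
                 for row in df.itertuples()}
        return cls(table=table, **kwargs)

    def lookup(self, atom: AtomRecord) -> Tuple[float, float, float]:
        hit = self.table.get(atom.atom_name)
        if hit is not None:
            return hit
        hit = self.table.get(f"element:{atom.element}")
        if hit is not None:
            rstar, eps, _ = hit
            if self.strict:
                raise ValueError(f"no partial charge for atom {atom.atom_name!r}")
            logger.warning("atom %s: element fallback parameters, charge 0", atom.atom_name)
            return rstar, eps, 0.0
        raise ValueError(f"no energy parameters for atom {atom.atom_name!r} "
                         f"(element {atom.element!r})")


def _combined(params: EnergyParams, atom_i: AtomRecord, atom_j: AtomRecord,
              ) -> Tuple[float, float, float, float]:
    ri, ei, qi = params.lookup(atom_i)
    rj, ej, qj = params.lookup(atom_j)
    return ri + rj, math.sqrt(ei * ej), qi, qj


def _distance(atom_i: AtomRecord, atom_j: AtomRecord) -> float:
    return math.dist((atom_i.x, atom_i.y, atom_i.z), (atom_j.x, atom_j.y, atom_j.z))


def lj_term(atom_i: AtomRecord, atom_j: AtomRecord, params: EnergyParams,
            r: Optional[float] = None) -> float:
    """12-6 Lennard-Jones energy of one atom pair, via the A/B form.

    A = eps* R*^12, B = 2 eps* R*^6, E = A/r^12 - B/r^6; the minimum is
    exactly -eps*_ij at r = R*_ij.
    """
    r = _distance(atom_i, atom_j) if r is None else r
    if r <= 0:
        raise ValueError("zero interatomic distance")
    rstar, eps, _, _ = _combined(params, atom_i, atom_j)
    a = eps * rstar ** 12
    b = 2.0 * eps * rstar ** 6
    return a / r ** 12 - b / r ** 6


def coulomb_term(atom_i: AtomRecord, atom_j: AtomRecord, params: EnergyParams,
                 r: Optional[float] = None) -> float:
    """Coulomb energy k q_i q_j / (eps r); eps = r when distance-dependent."""
    r = _distance(atom_i, atom_j) if r is None else r
    if r <= 0:
        raise ValueError("zero interatomic distance")
    _, _, qi, qj = _combined(params, atom_i, atom_j)
    eps = r if params.distance_dependent_dielectric else params.dielectric
    return params.coulomb_constant * qi * qj / (eps * r)


def residue_pair_energy(atoms_i: Sequence[AtomRecord], atoms_j: Sequence[AtomRecord],
                        params: EnergyParams) -> float:
    """Total LJ + Coulomb energy over all inter-residue heavy-atom pairs.

    Pairs farther apart than the evaluation shell (default 10 Å, where both
    terms are negligible at this scale) contribute nothing.
    """
    shell = params.evaluation_shell
    total = 0.0
    for ai in atoms_i:
        if ai.is_hydrogen:
            continue
        for aj in atoms_j:
            if aj.is_hydrogen:
                continue
            r = _distance(ai, aj)
            if r > shell:
                continue
            total += lj_term(ai, aj, params, r) + coulomb_term(ai, aj, params, r)
    return total


@dataclass
class PairEnergyMatrix:
    """Mean amino-acid × nucleotide interaction energies, DOT vs non-DOT."""

    dot_energy: pd.DataFrame
    dot_count: pd.DataFrame
    nondot_energy: pd.DataFrame
    nondot_count: pd.DataFrame


def energy_matrix(structure: Structure, contacts: Sequence[ContactRecord],
                  dot_residues: Set[ResidueKey], params: EnergyParams,
                  decimals: int = 2) -> PairEnergyMatrix:
    """Mean pair energy per amino-acid × nucleotide cell at the interface.

    Each contacting residue/nucleotide pair contributes one energy (sum over
    its atom pairs); cells average over pairs, stratified by whether the
    protein residue lies in a DOT region. Cells with no pairs report 0.00
    with count 0.
    """
    def blank() -> pd.DataFrame:
        return pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=list(NUCLEOTIDES))

    sums = {True: blank(), False: blank()}
    counts = {True: blank(), False: blank()}
    res_atoms = structure.residue_atoms()
    for c in contacts:
        aa, nt = c.protein_residue.res_name, c.nucleotide.res_name
        if aa not in sums[True].index or nt not in sums[True].columns:
            continue
        e = residue_pair_energy(res_atoms[c.protein_residue],
                                res_atoms[c.nucleotide], params)
        stratum = c.protein_residue in dot_residues
        sums[stratum].at[aa, nt] += e
        counts[stratum].at[aa, nt] += 1

    def mean(stratum: bool) -> pd.DataFrame:
        with np.errstate(invalid="ignore"):
            m = sums[stratum] / counts[stratum]
        return m.fillna(0.0).map(lambda v: round_half_up(v, decimals))

    return PairEnergyMatrix(dot_energy=mean(True), dot_count=counts[True].astype(int),
                            nondot_energy=mean(False),
                            nondot_count=counts[False].astype(int))
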