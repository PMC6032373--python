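"""Shared fixtures: synthetic structures with known ground truth and
brute-force oracles independent of the library's implementation paths."""

from __future__ import annotations

import numpy as np
import pytest

from dotrna import dot_detection as dd
from dotrna import interface_stats as ist
from dotrna import structure_io as sio
from dotrna import synthetic as syn
from dotrna.structure_io import AtomRecord, ResidueKey, Structure


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_structure(rng: np.random.Generator, n_protein: int = 50,
                     n_rna: int = 10, box: float = 25.0) -> Structure:
    """Random atom clouds: n_protein residues (3 atoms) + n_rna nucleotides
    (2 atoms), uniformly placed in a box so contacts arise by chance."""
    atoms = []
    aas = sio.AMINO_ACIDS
    for i in range(n_protein):
        key = ResidueKey("A", i + 1, "", aas[int(rng.integers(0, 20))])
        base = rng.uniform(0, box, size=3)
        for name, elem in (("N", "N"), ("CA", "C"), ("C", "C")):
            p = base + rng.normal(0, 0.8, size=3)
            atoms.append(AtomRecord(key, name, elem, *p))
    for j in range(n_rna):
        nt = "ACGU"[int(rng.integers(0, 4))]
        key = ResidueKey("R", j + 1, "", nt)
        base = rng.uniform(0, box, size=3)
        for name, elem in (("P", "P"), ("C1'", "C")):
            p = base + rng.normal(0, 0.8, size=3)
            atoms.append(AtomRecord(key, name, elem, *p))
    return Structure(atoms=atoms, chain_kinds={"A": "protein", "R": "rna"})


def brute_force_contacts(structure: Structure, cutoff: float):
    """All-pairs reference for contact detection (no spatial index)."""
    res_atoms = structure.residue_atoms()
    prot = [k for k in res_atoms if structure.chain_kinds[k.chain_id] == "protein"]
    rna = [k for k in res_atoms if structure.chain_kinds[k.chain_id] == "rna"]
    out = {}
    for pk in prot:
        pxyz = np.array([[a.x, a.y, a.z] for a in res_atoms[pk] if not a.is_hydrogen])
        for nk in rna:
            nxyz = np.array([[a.x, a.y, a.z] for a in res_atoms[nk] if not a.is_hydrogen])
            d = np.sqrt(((pxyz[:, None, :] - nxyz[None, :, :]) ** 2).sum(axis=2)).min()
            if d <= cutoff:
                out[(pk, nk)] = float(d)
    return out


def feasible_spec(rng: np.random.Generator) -> syn.FixtureSpec:
    """A random fixture spec that is geometrically realisable."""
    while True:
        spec = syn.random_fixture_spec(rng)
        try:
            syn.generate_pair(spec)
        except syn.InfeasibleFixture:
            continue
        return spec


def analyze_fixture(spec: syn.FixtureSpec):
    """Generate a fixture pair and push it through parsing + DOT detection."""
    free_text, bound_text, truth = syn.generate_pair(spec)
    free = sio.read_structure(free_text)
    bound = sio.read_structure(bound_text)
    pair = dd.StructurePair(free, bound, dd.build_mapping(free, bound))
    regions = dd.detect(pair)
    dot = {k for r in regions for k in r.residues}
    return bound, pair, regions, dot, truth


def count_tables_for(specs, cutoff: float = 3.5):
    tables = []
    for spec in specs:
        bound, _, _, dot, _ = analyze_fixture(spec)
        contacts = ist.find_contacts(bound, cutoff, dot)
        tables.append(ist.build_count_table(bound, dot, contacts))
    return tables
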