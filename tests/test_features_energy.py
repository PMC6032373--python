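"""Shrake-Rupley SASA, relative accessibility, and LJ + Coulomb energies."""

import math

import numpy as np
import pytest

from dotrna import features_energy as fe
from dotrna import interface_stats as ist
from dotrna import structure_io as sio
from dotrna import synthetic as syn
from dotrna.features_energy import EnergyParams
from dotrna.structure_io import AtomRecord, ResidueKey, Structure


def _atom(name="CA", elem="C", x=0.0, y=0.0, z=0.0, num=1, res="ALA", chain="A"):
    return AtomRecord(ResidueKey(chain, num, "", res), name, elem, x, y, z)


@pytest.fixture(scope="module")
def params():
    return EnergyParams.default()


@pytest.fixture(scope="module")
def unit_charge_params():
    # two synthetic atom types with unit charges for closed-form checks
    return EnergyParams(table={"XP": (1.0, 0.5, 1.0), "XN": (1.0, 0.5, 1.0),
                               "element:C": (1.908, 0.086, 0.0)})


class TestSASA:
    def test_isolated_atom_closed_form(self):
        st = Structure(atoms=[_atom("CB")], chain_kinds={"A": "protein"})
        sasa = fe.compute_sasa(st)
        exact = 4 * math.pi * (1.87 + 1.4) ** 2
        assert sasa[_atom("CB").key] == pytest.approx(exact, rel=0.01)

    def test_enclosed_atom_is_buried(self):
        centre = _atom("CB")
        shell = []
        pts = fe._fibonacci_sphere(80) * 2.2
        for i, p in enumerate(pts):
            shell.append(_atom("CB", x=p[0], y=p[1], z=p[2], num=i + 2))
        st = Structure(atoms=[centre] + shell, chain_kinds={"A": "protein"})
        sasa = fe.compute_sasa(st)
        assert sasa[centre.key] < 1.0

    def test_two_overlapping_atoms_symmetric(self):
        a = _atom("CB", num=1)
        b = _atom("CB", num=2, x=2.0)
        st = Structure(atoms=[a, b], chain_kinds={"A": "protein"})
        sasa = fe.compute_sasa(st)
        isolated = 4 * math.pi * (1.87 + 1.4) ** 2
        assert sasa[a.key] < isolated
        assert sasa[a.key] == pytest.approx(sasa[b.key], rel=0.02)

    def test_unknown_element_is_error(self):
        st = Structure(atoms=[_atom("FE", elem="FE")], chain_kinds={"A": "protein"})
        with pytest.raises(ValueError, match="FE"):
            fe.compute_sasa(st)

    def test_point_doubling_converges(self):
        spec = syn.FixtureSpec(n_residues=8, seed=4, n_nucleotides=1)
        _, bound_text, _ = syn.generate_pair(spec)
        st = sio.read_structure(bound_text)
        keys = st.residues("protein")
        t1 = sum(fe.compute_sasa(st, n_points=960, keys=keys).values())
        t2 = sum(fe.compute_sasa(st, n_points=1920, keys=keys).values())
        assert abs(t2 - t1) / t1 < 0.005

    def test_matches_independent_implementation(self):
        biotite_struc = pytest.importorskip("biotite.structure")
        import io
        import biotite.structure.io.pdb as bpdb
        spec = syn.FixtureSpec(n_residues=10, seed=3, n_nucleotides=1)
        _, bound_text, _ = syn.generate_pair(spec)
        st = sio.read_structure(bound_text)
        mine = sum(fe.compute_sasa(st, keys=st.residues("protein")).values())
        arr = bpdb.PDBFile.read(io.StringIO(bound_text)).get_structure(model=1)
        arr = arr[arr.chain_id == "A"]
        radii = np.array([fe.load_vdw_radii()[e] for e in arr.element])
        theirs = biotite_struc.sasa(arr, probe_radius=1.4, point_number=960,
                                    vdw_radii=radii).sum()
        assert mine == pytest.approx(theirs, rel=0.01)

    def test_rigid_body_invariance(self, rng):
        spec = syn.FixtureSpec(n_residues=6, seed=9, n_nucleotides=1)
        _, bound_text, _ = syn.generate_pair(spec)
        st = sio.read_structure(bound_text)
        rot, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = Structure(
            atoms=[AtomRecord(a.key, a.atom_name, a.element,
                              *(rot @ np.array([a.x, a.y, a.z]) + 7.5))
                   for a in st.atoms],
            chain_kinds=st.chain_kinds)
        s1 = sum(fe.compute_sasa(st, keys=st.residues("protein")).values())
        s2 = sum(fe.compute_sasa(moved, keys=moved.residues("protein")).values())
        assert s2 == pytest.approx(s1, rel=0.01)


class TestRelativeSASA:
    def test_scaling(self):
        key = ResidueKey("A", 1, "", "ALA")
        ref = {"ALA": 129.0}
        assert fe.relative_sasa({key: 129.0}, ref)[key] == pytest.approx(100.0)
        assert fe.relative_sasa({key: 0.0}, ref)[key] == 0.0
        assert fe.relative_sasa({key: 64.5}, ref)[key] == pytest.approx(50.0)

    def test_missing_reference_is_error(self):
        key = ResidueKey("A", 1, "", "ALA")
        with pytest.raises(ValueError, match="ALA"):
            fe.relative_sasa({key: 10.0}, {"GLY": 104.0})

    @pytest.mark.parametrize("dot,prot,expected", [
        (41.13, 20.391, 2.017), (52.168, 40.822, 1.278), (33.3, 33.3, 1.0)])
    def test_fold_difference(self, dot, prot, expected):
        assert fe.fold_difference(dot, prot) == expected

    def test_comparison_table(self):
        keys = [ResidueKey("A", i, "", "MET") for i in range(1, 5)]
        rasa = {keys[0]: 40.0, keys[1]: 42.0, keys[2]: 20.0, keys[3]: 22.0}
        dot = {keys[0], keys[1]}
        tab = fe.rasa_comparison_table(rasa, dot)
        assert tab.at["MET", "rasa_dot"] == pytest.approx(41.0)
        assert tab.at["MET", "rasa_protein"] == pytest.approx(31.0)
        assert tab.at["MET", "fold_difference"] == pytest.approx(41.0 / 31.0, abs=5e-4)
        assert math.isnan(tab.at["ARG", "fold_difference"])


class TestLJTerm:
    def test_minimum_identity(self, unit_charge_params):
        a = _atom("XP", num=1)
        b = _atom("XN", num=2, x=2.0)  # r = R*_ij = 1 + 1
        e = fe.lj_term(a, b, unit_charge_params)
        assert e == pytest.approx(-0.5, abs=1e-12)

    def test_long_range_decay(self, unit_charge_params):
        a = _atom("XP", num=1)
        b = _atom("XN", num=2, x=20.0)  # 10 R*
        assert abs(fe.lj_term(a, b, unit_charge_params)) < 1e-4 * 0.5

    def test_zero_crossing_bracketed_by_scan(self, unit_charge_params):
        a = _atom("XP", num=1)
        root = 2.0 * 2 ** (-1 / 6)
        assert fe.lj_term(a, _atom("XN", num=2, x=root), unit_charge_params) == \
            pytest.approx(0.0, abs=1e-12)
        rs = np.linspace(root - 0.2, root + 0.2, 81)
        es = [fe.lj_term(a, _atom("XN", num=2, x=r), unit_charge_params) for r in rs]
        signs = np.sign(es)
        assert signs[0] > 0 and signs[-1] < 0  # repulsive inside, attractive outside

    def test_local_minimum_at_rstar(self, params):
        a = _atom("CA", num=1)
        at_min = fe.lj_term(a, _atom("CA", num=2, x=2 * 1.908), params)
        for dr in (-0.1, 0.1):
            assert at_min <= fe.lj_term(a, _atom("CA", num=2, x=2 * 1.908 + dr), params)

    def test_zero_distance_is_error(self, params):
        with pytest.raises(ValueError):
            fe.lj_term(_atom(num=1), _atom(num=2), params)


class TestCoulombTerm:
    def test_zero_charge(self, params):
        # element-fallback parameters carry zero charge
        a = _atom("CG", num=1)
        b = _atom("CD", num=2, x=3.0)
        assert fe.coulomb_term(a, b, params) == 0.0

    def test_unit_charges_closed_form(self, unit_charge_params):
        a = _atom("XP", num=1)
        b = _atom("XP", num=2, x=3.32)
        assert fe.coulomb_term(a, b, unit_charge_params) == \
            pytest.approx(332.0637 / 3.32, abs=1e-9)  # ~100 kcal/mol

    def test_dielectric_scaling(self, unit_charge_params):
        a, b = _atom("XP", num=1), _atom("XP", num=2, x=3.0)
        e1 = fe.coulomb_term(a, b, unit_charge_params)
        doubled = EnergyParams(table=unit_charge_params.table, dielectric=2.0)
        assert fe.coulomb_term(a, b, doubled) == pytest.approx(e1 / 2)

    def test_distance_dependent_dielectric(self, unit_charge_params):
        ddd = EnergyParams(table=unit_charge_params.table,
                           distance_dependent_dielectric=True)
        a, b = _atom("XP", num=1), _atom("XP", num=2, x=4.0)
        assert fe.coulomb_term(a, b, ddd) == pytest.approx(332.0637 / 16.0)


class TestResiduePairEnergy:
    def test_outside_shell_is_zero(self, unit_charge_params):
        a = [_atom("XP", num=1)]
        b = [_atom("XN", num=2, x=50.0)]
        assert fe.residue_pair_energy(a, b, unit_charge_params) == 0.0

    def test_single_atoms_reduce_to_lj(self):
        zero_q = EnergyParams(table={"XP": (1.0, 0.5, 0.0)})
        a = [_atom("XP", num=1)]
        b = [_atom("XP", num=2, x=2.0)]
        assert fe.residue_pair_energy(a, b, zero_q) == pytest.approx(-0.5, abs=1e-12)

    def test_matches_brute_force_double_loop(self, rng, unit_charge_params):
        atoms_a = [_atom("XP", num=1, x=x, y=y, z=z)
                   for x, y, z in rng.uniform(0, 6, size=(15, 3))]
        atoms_b = [_atom("XN", num=2, x=x + 4, y=y, z=z)
                   for x, y, z in rng.uniform(0, 6, size=(15, 3))]
        got = fe.residue_pair_energy(atoms_a, atoms_b, unit_charge_params)
        expected = 0.0
        for ai in atoms_a:
            for bj in atoms_b:
                r = math.dist((ai.x, ai.y, ai.z), (bj.x, bj.y, bj.z))
                if r > unit_charge_params.evaluation_shell:
                    continue
                rstar, eps = 2.0, 0.5
                expected += eps * ((rstar / r) ** 12 - 2 * (rstar / r) ** 6)
                expected += 332.0637 / r
        assert got == pytest.approx(expected, abs=1e-9)

    def test_symmetry(self, rng, unit_charge_params):
        atoms_a = [_atom("XP", num=1, x=x, y=y, z=z)
                   for x, y, z in rng.uniform(0, 5, size=(6, 3))]
        atoms_b = [_atom("XN", num=2, x=x + 3, y=y, z=z)
                   for x, y, z in rng.uniform(0, 5, size=(6, 3))]
        assert fe.residue_pair_energy(atoms_a, atoms_b, unit_charge_params) == \
            pytest.approx(fe.residue_pair_energy(atoms_b, atoms_a, unit_charge_params))

    def test_rigid_body_invariance(self, rng, unit_charge_params):
        atoms_a = [_atom("XP", num=1, x=x, y=y, z=z)
                   for x, y, z in rng.uniform(0, 5, size=(6, 3))]
        atoms_b = [_atom("XN", num=2, x=x + 3, y=y, z=z)
                   for x, y, z in rng.uniform(0, 5, size=(6, 3))]
        e1 = fe.residue_pair_energy(atoms_a, atoms_b, unit_charge_params)
        rot, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        move = lambda a: AtomRecord(a.key, a.atom_name, a.element,
                                    *(rot @ np.array([a.x, a.y, a.z]) + 11.0))
        e2 = fe.residue_pair_energy([move(a) for a in atoms_a],
                                    [move(b) for b in atoms_b], unit_charge_params)
        assert e2 == pytest.approx(e1, rel=1e-6)

    def test_missing_parameters_is_error(self):
        bare = EnergyParams(table={})
        with pytest.raises(ValueError, match="QQ"):
            fe.residue_pair_energy([_atom("QQ", elem="Q", num=1)],
                                   [_atom("QQ", elem="Q", num=2, x=3.0)], bare)


class TestEnergyMatrix:
    def test_single_pair_cell(self, params):
        spec = syn.FixtureSpec(n_residues=10, sequence="ARNDCQEGHI",
                               missing_free=[(2, 3)], contact_plan=[(2, 0, 3.0)],
                               seed=6)
        free_text, bound_text, truth = syn.generate_pair(spec)
        st = sio.read_structure(bound_text)
        dot = {k for k in st.residues("protein")
               if k.seq_num in truth["dot_residues"]}
        contacts = ist.find_contacts(st, 3.5, dot)
        em = fe.energy_matrix(st, contacts, dot, params)
        (aa, nt) = ("ARG", truth["rna_sequence"][0])
        assert em.dot_count.at[aa, nt] == 1
        res_atoms = st.residue_atoms()
        expected = fe.residue_pair_energy(
            res_atoms[contacts[0].protein_residue],
            res_atoms[contacts[0].nucleotide], params)
        assert em.dot_energy.at[aa, nt] == pytest.approx(expected, abs=0.005)

    def test_no_dot_contacts_gives_zero_count_matrix(self, params):
        spec = syn.FixtureSpec(n_residues=8, contact_plan=[(4, 0, 3.0)], seed=2)
        _, bound_text, _ = syn.generate_pair(spec)
        st = sio.read_structure(bound_text)
        contacts = ist.find_contacts(st, 3.5, set())
        em = fe.energy_matrix(st, contacts, set(), params)
        assert em.dot_count.to_numpy().sum() == 0
        assert em.nondot_count.to_numpy().sum() == len(contacts)
        assert (em.dot_energy.to_numpy() == 0).all()
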