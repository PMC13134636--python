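"""H-bond detection vs brute-force enumeration; frequencies; hub analysis."""

import numpy as np
import pytest

import macroperm as mp
from macroperm.ensemble_io import Atom, ConformerEnsemble, Frame, Topology
from macroperm.hbonds import HBondCriteria

from conftest import random_polar_frame


def _donor_acceptor_pair(d_da: float, angle_deg: float):
    """O-H···O geometry with exact D···A distance and D-H-A angle."""
    oh = 1.0
    d_pos = np.array([0.0, 0.0, 0.0])
    h_pos = np.array([oh, 0.0, 0.0])
    # place acceptor so that the H-D and H-A vectors subtend `angle_deg`
    theta = np.radians(180.0 - angle_deg)  # from the +x axis at H
    # solve |A - D| = d_da with A = H + t*(cos θ, sin θ, 0)
    b = 2 * oh * np.cos(theta)
    t = (-b + np.sqrt(b**2 - 4 * (oh**2 - d_da**2))) / 2.0
    a_pos = h_pos + t * np.array([np.cos(theta), np.sin(theta), 0.0])
    atoms = [
        Atom(index=0, element="O", name="OD", residue_id=1, residue_name="A",
             vdw_radius=1.52, is_polar=True, is_donor_heavy=True,
             is_acceptor=True, attached_h_indices=(1,), molecule_tag="solute"),
        Atom(index=1, element="H", name="HD", residue_id=1, residue_name="A",
             vdw_radius=1.20, is_polar=True, molecule_tag="solute"),
        Atom(index=2, element="O", name="OA", residue_id=2, residue_name="B",
             vdw_radius=1.52, is_polar=True, is_acceptor=True,
             molecule_tag="solute"),
    ]
    return Topology(atoms=atoms), Frame(coordinates=np.array([d_pos, h_pos, a_pos]))


def brute_force_events(frame, topology, criteria):
    """Independent triple enumeration applying the same cutoffs."""
    xyz = frame.coordinates
    found = set()
    for don in topology.atoms:
        if not (don.is_donor_heavy and don.attached_h_indices):
            continue
        for acc in topology.atoms:
            if not acc.is_acceptor or acc.index == don.index:
                continue
            if don.residue_id == acc.residue_id and not topology.bonds:
                continue  # same-residue pairs need a bond path of >= 3
            if np.linalg.norm(xyz[don.index] - xyz[acc.index]) > criteria.max_da_distance:
                continue
            for h in don.attached_h_indices:
                v1 = xyz[don.index] - xyz[h]
                v2 = xyz[acc.index] - xyz[h]
                cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cos, -1, 1))) >= criteria.min_dha_angle:
                    found.add((don.index, h, acc.index))
    return found


class TestDetection:
    def test_ideal_linear_geometry(self):
        topo, frame = _donor_acceptor_pair(2.8, 180.0)
        events = mp.detect_hbonds(frame, topo)
        assert len(events) == 1
        ev = events[0]
        assert (ev.donor_heavy, ev.hydrogen, ev.acceptor) == (0, 1, 2)
        assert ev.da_distance == pytest.approx(2.8)
        assert ev.dha_angle == pytest.approx(180.0)
        assert ev.kind == "intramolecular"

    def test_distance_cutoff(self):
        topo, frame = _donor_acceptor_pair(4.0, 180.0)
        assert mp.detect_hbonds(frame, topo) == []

    def test_angle_cutoff(self):
        topo, frame = _donor_acceptor_pair(2.8, 120.0)
        assert mp.detect_hbonds(frame, topo) == []
        loose = HBondCriteria(min_dha_angle=100.0)
        assert len(mp.detect_hbonds(frame, topo, loose)) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        topo, frame = random_polar_frame(rng, n_heavy=int(rng.integers(8, 20)))
        criteria = HBondCriteria()
        ours = {
            (e.donor_heavy, e.hydrogen, e.acceptor)
            for e in mp.detect_hbonds(frame, topo, criteria)
        }
        assert ours == brute_force_events(frame, topo, criteria)

    def test_monotone_under_stricter_criteria(self):
        rng = np.random.default_rng(42)
        topo, frame = random_polar_frame(rng, n_heavy=25, box=6.0)
        loose = len(mp.detect_hbonds(frame, topo,
                                     HBondCriteria(3.8, 120.0)))
        default = len(mp.detect_hbonds(frame, topo, HBondCriteria()))
        strict = len(mp.detect_hbonds(frame, topo,
                                      HBondCriteria(3.0, 150.0)))
        assert strict <= default <= loose

    def test_same_residue_needs_three_bonds(self):
        # N-H donating to an O two bonds away in the same residue: excluded
        atoms = [
            Atom(index=0, element="N", name="N", residue_id=1, residue_name="R",
                 vdw_radius=1.55, is_donor_heavy=True, attached_h_indices=(1,),
                 molecule_tag="solute"),
            Atom(index=1, element="H", name="H", residue_id=1, residue_name="R",
                 vdw_radius=1.2, molecule_tag="solute"),
            Atom(index=2, element="C", name="C", residue_id=1, residue_name="R",
                 vdw_radius=1.7, molecule_tag="solute"),
            Atom(index=3, element="O", name="O", residue_id=1, residue_name="R",
                 vdw_radius=1.52, is_acceptor=True, molecule_tag="solute"),
        ]
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1.4, 0], [2.8, 0, 0.0]])
        short_path = Topology(atoms=atoms, bonds=[(0, 1), (0, 2), (2, 3)])
        assert mp.detect_hbonds(Frame(coordinates=coords), short_path) == []
        # a 3-bond path makes the same geometry count
        long_path = Topology(atoms=atoms, bonds=[(0, 1), (0, 2), (2, 3)])
        long_path.bonds = [(0, 1), (0, 2), (2, 3)]
        atoms4 = atoms + [
            Atom(index=4, element="C", name="C2", residue_id=1, residue_name="R",
                 vdw_radius=1.7, molecule_tag="solute")
        ]
        coords4 = np.vstack([coords, [[0.0, 2.8, 0.0]]])
        rerouted = Topology(atoms=atoms4, bonds=[(0, 1), (0, 2), (2, 4), (4, 3)])
        assert len(mp.detect_hbonds(Frame(coordinates=coords4), rerouted)) == 1

    def test_solvent_partner_sets_kind(self):
        topo, frame = _donor_acceptor_pair(2.8, 180.0)
        solvent_acc = Atom(
            index=2, element="O", name="OW", residue_id=2, residue_name="HOH",
            vdw_radius=1.52, is_polar=True, is_acceptor=True,
            molecule_tag="solvent",
        )
        topo2 = Topology(atoms=[topo.atoms[0], topo.atoms[1], solvent_acc])
        events = mp.detect_hbonds(frame, topo2)
        assert len(events) == 1 and events[0].kind == "solute-solvent"


class TestFrequencies:
    def test_always_present_is_one(self):
        topo, frame = _donor_acceptor_pair(2.8, 180.0)
        ens = ConformerEnsemble(topology=topo, frames=[frame, frame, frame])
        table = mp.hbond_frequencies(ens)
        assert table.pair_frequencies[(0, 2)] == pytest.approx(1.0)
        assert table.total_intramolecular == pytest.approx(1.0)

    def test_weighted_presence(self):
        topo, present = _donor_acceptor_pair(2.8, 180.0)
        _, absent = _donor_acceptor_pair(4.5, 180.0)
        ens = ConformerEnsemble(topology=topo, frames=[present, absent])
        w = np.array([0.8325, 0.1675])
        table = mp.hbond_frequencies(ens, weights=w)
        assert table.pair_frequencies[(0, 2)] == pytest.approx(0.8325)

    def test_absent_named_bond_reported_as_zero(self, macrocycle):
        topo, _, open_ = macrocycle
        ens = ConformerEnsemble(topology=topo, frames=[open_])
        table = mp.hbond_frequencies(ens)
        assert set(table.named_frequencies) == {"Hb1", "Hb2", "Hb3", "Hb4"}
        assert all(v == 0.0 for v in table.named_frequencies.values())

    def test_frequencies_bounded_by_one(self, macrocycle):
        topo, closed, open_ = macrocycle
        ens = ConformerEnsemble(topology=topo,
                                frames=[closed, closed, open_, closed])
        table = mp.hbond_frequencies(ens)
        assert all(0.0 <= f <= 1.0 + 1e-12
                   for f in table.pair_frequencies.values())


class TestHub:
    def test_planted_bridge_degree_four(self, macrocycle):
        topo, closed, _ = macrocycle
        ens = ConformerEnsemble(topology=topo, frames=[closed])
        hub = mp.hub_summary(mp.hbond_frequencies(ens), topo)
        assert hub.degree == 4
        assert hub.donor_and_acceptor is True
        assert len(hub.partner_residues) == 4

    def test_no_bonds_degree_zero(self, macrocycle):
        topo, _, open_ = macrocycle
        ens = ConformerEnsemble(topology=topo, frames=[open_])
        hub = mp.hub_summary(mp.hbond_frequencies(ens), topo)
        assert hub.degree == 0 and hub.donor_and_acceptor is False

    def test_threshold_monotonicity(self, macrocycle):
        topo, closed, open_ = macrocycle
        ens = ConformerEnsemble(topology=topo, frames=[closed, open_])
        table = mp.hbond_frequencies(ens)  # planted bonds at frequency 0.5
        degrees = [
            mp.hub_summary(table, topo, threshold=t).degree
            for t in (0.1, 0.4, 0.6, 1.1)
        ]
        assert degrees == sorted(degrees, reverse=True)
        assert degrees[-1] == 0

    def test_unknown_residue_errors(self, macrocycle):
        topo, closed, _ = macrocycle
        ens = ConformerEnsemble(topology=topo, frames=[closed])
        with pytest.raises(ValueError, match="not in topology"):
            mp.hub_summary(mp.hbond_frequencies(ens), topo, residue_id=99)
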