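"""GB/SA solvation: Born-ion closed forms, descreening quadrature, ΔG_loss."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import macroperm as mp
from macroperm.ensemble_io import Atom, ConformerEnsemble, Frame, Topology
from macroperm.solvation import (
    CHLOROFORM,
    COULOMB_KCAL,
    WATER,
    _hct_integral,
    effective_born_radii,
)
from macroperm.synthetic import make_born_ion


def born_energy(q, a, eps):
    """Independent Born-ion closed form, kcal/mol."""
    return -0.5 * COULOMB_KCAL * (1.0 - 1.0 / eps) * q**2 / a


def _toy_molecule(rng, n=5):
    pos = rng.uniform(0, 4, (n, 3))
    charges = rng.uniform(-0.5, 0.5, n)
    atoms = [
        Atom(index=i, element="C", name=f"C{i}", residue_id=1, residue_name="TOY",
             partial_charge=float(charges[i]), vdw_radius=1.7,
             molecule_tag="solute")
        for i in range(n)
    ]
    return Topology(atoms=atoms), Frame(coordinates=pos)


class TestBornRadii:
    def test_isolated_atom_equals_intrinsic_minus_offset(self):
        topo, frame = make_born_ion(1.5, 0.0)
        r = effective_born_radii(frame, topo, offset=0.09)
        assert r[0] == pytest.approx(1.41, abs=1e-12)

    def test_distant_atoms_unperturbed(self):
        atoms = [
            Atom(index=i, element="C", name=f"C{i}", residue_id=1,
                 residue_name="T", vdw_radius=1.5, molecule_tag="solute")
            for i in range(2)
        ]
        topo = Topology(atoms=atoms)
        frame = Frame(coordinates=np.array([[0.0, 0, 0], [100.0, 0, 0]]))
        r = effective_born_radii(frame, topo)
        assert np.allclose(r, 1.41, atol=1e-6)

    def test_contact_atoms_grow(self):
        atoms = [
            Atom(index=i, element="C", name=f"C{i}", residue_id=1,
                 residue_name="T", vdw_radius=1.5, molecule_tag="solute")
            for i in range(2)
        ]
        topo = Topology(atoms=atoms)
        frame = Frame(coordinates=np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        r = effective_born_radii(frame, topo)
        assert (r > 1.41).all()

    def test_radius_below_offset_errors(self):
        topo, frame = make_born_ion(0.05, 0.0)
        with pytest.raises(ValueError, match="offset"):
            effective_born_radii(frame, topo, offset=0.09)

    @pytest.mark.parametrize("r,s,rho", [(3.0, 1.2, 1.4), (2.0, 1.5, 1.0),
                                         (4.5, 0.8, 1.3), (1.2, 1.5, 0.9)])
    def test_descreening_integral_matches_quadrature(self, r, s, rho):
        """H(r, s; ρ) equals the direct volume integral of 1/x⁴ / 4π.

        Integration over the descreening sphere (radius s at distance r)
        excluding the region within ρ of the descreened atom's center.
        """
        # spherical shells around the descreened atom's center
        radii = np.linspace(max(rho, r - s), r + s, 4001)
        shell = np.zeros_like(radii)
        for k, x in enumerate(radii):
            if x <= 0:
                continue
            # half-angle of the cap of radius-x sphere inside the descreener
            cos_t = (x**2 + r**2 - s**2) / (2 * x * r)
            cos_t = np.clip(cos_t, -1.0, 1.0)
            shell[k] = 2 * np.pi * x**2 * (1 - cos_t) / x**4
        numeric = np.trapezoid(shell, radii) / (4 * np.pi)
        analytic = float(_hct_integral(np.array(r), np.array(s), np.array(rho)))
        assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestGBEnergy:
    def test_zero_charges_zero_energy(self):
        topo, frame = make_born_ion(2.0, 0.0)
        assert mp.gb_polarization_energy(frame, [0.0], [2.0]) == 0.0

    def test_equal_dielectrics_zero_energy(self):
        topo, frame = make_born_ion(2.0, 1.0)
        assert mp.gb_polarization_energy(frame, [1.0], [2.0], 4.0, 4.0) == 0.0

    def test_born_ion_closed_form(self):
        topo, frame = make_born_ion(2.0, 1.0)
        e = mp.gb_polarization_energy(frame, [1.0], [2.0], 1.0, 78.5)
        assert e == pytest.approx(born_energy(1.0, 2.0, 78.5), rel=1e-12)
        assert e == pytest.approx(-81.957, abs=1e-3)

    def test_random_born_ions(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            q = rng.uniform(-2, 2)
            a = rng.uniform(0.8, 4.0)
            eps = rng.uniform(1.5, 100.0)
            topo, frame = make_born_ion(a, q)
            e = mp.gb_polarization_energy(frame, [q], [a], 1.0, eps)
            assert e == pytest.approx(born_energy(q, a, eps), rel=1e-6)

    def test_g_polar_nonpositive_and_monotone_in_eps(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            topo, frame = _toy_molecule(rng)
            radii = effective_born_radii(frame, topo)
            prev = 0.0
            for eps in [1.5, 4.81, 20.0, 78.5]:
                e = mp.gb_polarization_energy(
                    frame, topo.partial_charges(), radii, 1.0, eps)
                assert e <= 1e-12
                assert e <= prev + 1e-12  # more polar solvent stabilizes more
                prev = e

    def test_nonpositive_born_radius_errors(self):
        topo, frame = make_born_ion(2.0, 1.0)
        with pytest.raises(ValueError, match="Born radii"):
            mp.gb_polarization_energy(frame, [1.0], [-1.0])


class TestSolvationFreeEnergy:
    def test_neutral_atom_is_pure_surface_term(self):
        topo, frame = make_born_ion(1.7, 0.0)
        ens = ConformerEnsemble(topology=topo, frames=[frame])
        res = mp.solvation_free_energy(ens, WATER)
        surf = mp.shrake_rupley(frame, topo)
        expected = WATER.surface_tension_gamma * surf.total_sasa + WATER.surface_offset_b
        assert res.g_solv_mean == pytest.approx(expected, rel=1e-9)
        assert res.g_polar_mean == 0.0

    def test_g_solv_is_sum_of_terms(self):
        rng = np.random.default_rng(3)
        topo, frame = _toy_molecule(rng)
        ens = ConformerEnsemble(topology=topo, frames=[frame])
        res = mp.solvation_free_energy(ens, WATER)
        assert np.allclose(
            res.per_frame_g_solv,
            res.per_frame_g_polar + res.per_frame_g_nonpolar, atol=1e-9,
        )

    def test_weights_select_frames(self, macrocycle):
        topo, closed, open_ = macrocycle
        ens = ConformerEnsemble(topology=topo, frames=[closed, open_])
        res = mp.solvation_free_energy(ens, WATER, weights=np.array([1.0, 0.0]))
        assert res.g_solv_mean == pytest.approx(res.per_frame_g_solv[0])

    def test_polar_solvent_stabilizes_more(self, macrocycle):
        topo, closed, _ = macrocycle
        ens = ConformerEnsemble(topology=topo, frames=[closed])
        g_w = mp.solvation_free_energy(ens, WATER)
        g_c = mp.solvation_free_energy(ens, CHLOROFORM)
        assert g_w.g_polar_mean <= g_c.g_polar_mean <= 0.0


class TestDeltaGLoss:
    def test_identical_inputs_zero(self, macrocycle):
        topo, closed, _ = macrocycle
        ens = ConformerEnsemble(topology=topo, frames=[closed])
        assert mp.delta_g_loss(ens, ens, WATER, WATER) == pytest.approx(0.0)

    def test_apolar_molecule_zero(self):
        atoms = [
            Atom(index=i, element="C", name=f"C{i}", residue_id=1,
                 residue_name="T", vdw_radius=1.7, molecule_tag="solute")
            for i in range(3)
        ]
        topo = Topology(atoms=atoms)
        frame = Frame(coordinates=np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0.0]]))
        ens = ConformerEnsemble(topology=topo, frames=[frame])
        # same gamma/b in both solvents -> nonpolar terms cancel exactly
        assert mp.delta_g_loss(ens, ens) == pytest.approx(0.0, abs=1e-12)

    def test_born_ion_two_solvent_difference(self):
        """ΔG_loss of the Born ion from two closed forms differenced.

        -½·332.06·q²/a·[(1-1/4.81) - (1-1/78.5)] = +16.20 kcal/mol for
        q = +1 e, a = 2.0 Å (the GB self-term uses the offset-reduced Born
        radius, so the intrinsic radius is chosen to land at a = 2.0).
        """
        topo, frame = make_born_ion(2.09, 1.0)  # 2.09 - 0.09 offset = 2.00
        ens = ConformerEnsemble(topology=topo, frames=[frame])
        expected = born_energy(1.0, 2.0, 4.81) - born_energy(1.0, 2.0, 78.5)
        assert expected == pytest.approx(16.201, abs=1e-3)
        assert mp.delta_g_loss(ens, ens) == pytest.approx(expected, rel=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(17)
        topo, frame = _toy_molecule(rng)
        ens = ConformerEnsemble(topology=topo, frames=[frame])
        base = mp.delta_g_loss(ens, ens)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0])
        moved = Frame(coordinates=rot.apply(frame.coordinates) + [5.0, -3.0, 1.0])
        ens2 = ConformerEnsemble(topology=topo, frames=[moved])
        assert mp.delta_g_loss(ens2, ens2) == pytest.approx(base, rel=1e-9)

    def test_more_polarity_costs_more(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            pos = rng.uniform(0, 4, (4, 3))
            base_q = rng.uniform(-0.3, 0.3, 4)
            losses = []
            for scale in (1.0, 1.5, 2.0):
                atoms = [
                    Atom(index=i, element="C", name=f"C{i}", residue_id=1,
                         residue_name="T", partial_charge=float(base_q[i] * scale),
                         vdw_radius=1.7, molecule_tag="solute")
                    for i in range(4)
                ]
                ens = ConformerEnsemble(
                    topology=Topology(atoms=atoms),
                    frames=[Frame(coordinates=pos)],
                )
                losses.append(mp.delta_g_loss(ens, ens))
            assert losses[0] < losses[1] < losses[2]

    def test_topology_mismatch_errors(self, macrocycle):
        topo, closed, _ = macrocycle
        ens = ConformerEnsemble(topology=topo, frames=[closed])
        other_topo, other_frame = make_born_ion(2.0, 0.0)
        other = ConformerEnsemble(topology=other_topo, frames=[other_frame])
        with pytest.raises(ValueError, match="topology"):
            mp.delta_g_loss(ens, other)
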