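"""Synthetic inputs with known ground truth for every pipeline stage.

The generators replace molecular-dynamics production runs with analytic
stand-ins whose correct answers are known in closed form:

* :func:`make_macrocycle_topology` — a ring-of-residues toy macrobicycle
  whose *closed* template plants four hydrogen bonds between the bridging
  residue and four distinct partner residues (the bridge donates two and
  accepts two), and whose *open* template splays all donor–acceptor pairs
  beyond 5 Å;
* :func:`make_two_state_ensemble` — frames drawn from the two templates
  with Boltzmann state probabilities at the simulation temperature, with
  per-frame energies (E_open = 0, E_closed = ΔE plus small Gaussian
  noise) chosen so that reweighting to the target temperature recovers a
  planted closed population;
* :func:`make_library` — a compound library obeying a planted linear law
  log10(P_e) = slope·x + intercept + N(0, noise_sd) whose population
  Pearson correlation is analytically computable;
* :func:`make_born_ion` — a single charged sphere, the analytic oracle
  for the generalized-Born and SASA machinery.

Every generator is a pure function of its spec plus one integer seed;
independent substreams are split off with ``numpy.random.SeedSequence``.

These are geometric and statistical stand-ins, not physical molecules:
energies are state labels plus noise, not force-field evaluations, and
the "residues" are rigid bead clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble_io import Atom, ConformerEnsemble, Frame, PermeabilityTable, Topology
from .reweighting import KB_KJ_PER_MOL_K

__all__ = [
    "TwoStateSpec",
    "LibrarySpec",
    "make_macrocycle_topology",
    "make_two_state_ensemble",
    "make_library",
    "make_born_ion",
    "two_state_energy_gap",
    "boltzmann_p_closed",
    "noise_sd_for_target_r",
]


def two_state_energy_gap(p_closed: float, temperature: float) -> float:
    """ΔE (kJ/mol) giving the stated closed population at ``temperature``."""
    if not (0 < p_closed < 1):
        raise ValueError("p_closed must be in (0, 1)")
    return -KB_KJ_PER_MOL_K * temperature * np.log(p_closed / (1.0 - p_closed))


def boltzmann_p_closed(energy_gap: float, temperature: float) -> float:
    """Closed population of the two-state system (E_open=0, E_closed=ΔE)."""
    return 1.0 / (1.0 + np.exp(energy_gap / (KB_KJ_PER_MOL_K * temperature)))


@dataclass
class TwoStateSpec:
    """Two-macrostate ensemble with a planted closed population.

    ``energy_gap`` defaults to the value that yields ``p_closed_target``
    at ``t_target``; frames are then drawn with Boltzmann probabilities at
    ``t_sim``, emulating a high-temperature trajectory that must be
    reweighted back down.
    """

    topology: Topology
    template_closed: Frame
    template_open: Frame
    n_frames: int = 1000
    p_closed_target: float = 0.115
    t_sim: float = 500.0
    t_target: float = 300.0
    energy_gap: float | None = None
    jitter_sd: float = 0.05       # Å; small enough not to flip classification
    energy_noise_sd: float = 0.1  # kJ/mol; small vs any planted gap >= 1 kJ/mol
    seed: int = 0

    def resolved_energy_gap(self) -> float:
        if self.energy_gap is not None:
            return self.energy_gap
        return two_state_energy_gap(self.p_closed_target, self.t_target)

    def p_closed_at(self, temperature: float) -> float:
        return boltzmann_p_closed(self.resolved_energy_gap(), temperature)


@dataclass
class LibrarySpec:
    """Compound library with a planted descriptor→log-permeability law."""

    n_compounds: int = 40
    slope: float = -3.0
    intercept: float = 0.5
    noise_sd: float = 0.1
    descriptor_range: tuple[float, float] = (0.0, 1.0)
    descriptor_name: str = "dce"
    series_label: str = "bridging-His"
    seed: int = 0

    def descriptor_sd(self) -> float:
        lo, hi = self.descriptor_range
        return (hi - lo) / np.sqrt(12.0)

    def population_pearson_r(self) -> float:
        """Analytic Pearson r of the planted law (uniform x, Gaussian noise)."""
        sx = self.descriptor_sd()
        signal = self.slope * sx
        return signal / np.sqrt(signal**2 + self.noise_sd**2)


def noise_sd_for_target_r(
    slope: float, descriptor_range: tuple[float, float], target_r: float
) -> float:
    """Noise level giving a planted population correlation of |target_r|."""
    if not (0 < abs(target_r) < 1):
        raise ValueError("target_r must be in (0, 1) in magnitude")
    sx = (descriptor_range[1] - descriptor_range[0]) / np.sqrt(12.0)
    return abs(slope) * sx * np.sqrt(1.0 / target_r**2 - 1.0)


# ---------------------------------------------------------------------------
# Toy macrobicycle
# ---------------------------------------------------------------------------

_NH_LEN = 1.0     # Å, donor N–H
_DA_LEN = 2.9     # Å, planted donor–acceptor distance
_OPEN_SHIFT = 7.0 # Å, radial displacement breaking all planted contacts


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_macrocycle_topology(
    n_residues: int = 8,
    bridge_position: int = 0,
    donors_per_residue: int = 1,
    acceptors_per_residue: int = 1,
    seed: int = 0,
) -> tuple[Topology, Frame, Frame]:
    """Toy macrobicycle topology plus closed/open template frames.

    Each residue carries one backbone carbon, ``donors_per_residue`` N–H
    groups and ``acceptors_per_residue`` O acceptors. The bridge residue's
    first donor nitrogen bears two hydrogens so it can donate to two
    different partners; in the closed template the bridge donates to
    residues b+1 and b+2 and accepts from b+3 and b+4 (indices mod n), all
    at ideal geometry (2.9 Å, collinear D–H···A). In the open template
    every non-bridge residue is displaced 7 Å radially, breaking every
    planted contact. Named bonds Hb1–Hb4 label the planted pairs.

    Returns ``(topology, closed_frame, open_frame)``.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues (bridge + 4 partners wraps)")
    if n_residues < 5:
        raise ValueError("need at least 5 residues for 4 distinct partners")
    if donors_per_residue < 1 or acceptors_per_residue < 1:
        raise ValueError("each residue needs >= 1 donor and >= 1 acceptor")
    if not (0 <= bridge_position < n_residues):
        raise ValueError("bridge_position out of range")

    b = bridge_position
    partners = [(b + k) % n_residues for k in (1, 2, 3, 4)]
    remote = [r for r in range(n_residues) if r != b and r not in partners]

    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    closed: list[np.ndarray] = []
    names_hb: dict[str, tuple[int, int]] = {}
    # per-residue bookkeeping: first donor N index, first acceptor O index
    donor_n: dict[int, int] = {}
    acceptor_o: dict[int, int] = {}
    residue_atoms: dict[int, list[int]] = {r: [] for r in range(n_residues)}

    def add_atom(element, name, res, pos, charge, is_donor=False, is_acc=False,
                 attached=()):
        idx = len(atoms)
        atoms.append(
            Atom(index=idx, element=element, name=name, residue_id=res,
                 residue_name="BRG" if res == b else "RES",
                 partial_charge=charge,
                 vdw_radius={"C": 1.70, "N": 1.55, "O": 1.52, "H": 1.20}[element],
                 is_polar=element in ("N", "O") or (element == "H" and attached),
                 is_donor_heavy=is_donor, is_acceptor=is_acc,
                 attached_h_indices=tuple(attached), molecule_tag="solute")
        )
        closed.append(np.asarray(pos, dtype=float))
        residue_atoms[res].append(idx)
        return idx

    def add_residue(res, site, outward, active_donor_pos=None, active_h_pos=None,
                    active_acceptor_pos=None, n_extra_h=1):
        """One residue: C at site, donors/acceptors strung along `outward`.

        ``active_*`` positions override the first donor/acceptor placement
        (used for the bridge and its four partners).
        """
        site = np.asarray(site, dtype=float)
        outward = _unit(np.asarray(outward, dtype=float))
        c = add_atom("C", "C", res, site, 0.2)
        offset = 1.4
        for k in range(donors_per_residue):
            if k == 0 and active_donor_pos is not None:
                npos = np.asarray(active_donor_pos, dtype=float)
                hpos = [np.asarray(p, dtype=float) for p in active_h_pos]
            else:
                npos = site + (offset + 1.5 * k) * outward
                hpos = [npos + _NH_LEN * outward]
            h_idx = []
            n_idx_placeholder = len(atoms)  # N goes in before its hydrogens
            n_idx = add_atom("N", f"N{k+1}", res, npos, -0.6)
            for j, hp in enumerate(hpos):
                h_idx.append(add_atom("H", f"H{k+1}{j+1}", res, hp, 0.35))
            # rebuild the N atom with donor flags now that H indices exist
            atoms[n_idx] = Atom(
                index=n_idx, element="N", name=f"N{k+1}", residue_id=res,
                residue_name=atoms[n_idx].residue_name, partial_charge=-0.6,
                vdw_radius=1.55, is_polar=True, is_donor_heavy=True,
                is_acceptor=False, attached_h_indices=tuple(h_idx),
                molecule_tag="solute")
            bonds.append((c, n_idx))
            bonds.extend((n_idx, h) for h in h_idx)
            if k == 0:
                donor_n[res] = n_idx
            assert n_idx_placeholder == n_idx
        offset_o = 1.4 + 1.5 * donors_per_residue
        perp = _unit(np.cross(outward, [0.0, 0.0, 1.0])
                     if abs(outward[2]) < 0.9 else np.cross(outward, [1.0, 0.0, 0.0]))
        for k in range(acceptors_per_residue):
            if k == 0 and active_acceptor_pos is not None:
                opos = np.asarray(active_acceptor_pos, dtype=float)
            else:
                opos = site + (offset_o + 1.5 * k) * outward + 1.2 * perp
            o_idx = add_atom("O", f"O{k+1}", res, opos, -0.5, is_acc=True)
            bonds.append((c, o_idx))
            if k == 0:
                acceptor_o[res] = o_idx

    # --- bridge residue: N with two H at the origin, its own acceptor O below
    n_b = np.array([0.0, 0.0, 0.0])
    h1_dir = np.array([1.0, 0.0, 0.0])
    h2_dir = np.array([-0.5, np.sqrt(3) / 2, 0.0])
    c_b = np.array([0.0, -1.4, 0.0])
    o_b = np.array([0.0, -2.6, 0.0])
    add_residue(
        b, c_b, outward=[0.0, 0.0, 1.0],
        active_donor_pos=n_b,
        active_h_pos=[n_b + _NH_LEN * h1_dir, n_b + _NH_LEN * h2_dir],
        active_acceptor_pos=o_b,
    )

    # --- acceptor partners: O collinear with a bridge N–H ray
    for label_i, (part, hdir) in enumerate(zip(partners[:2], (h1_dir, h2_dir))):
        opos = n_b + _DA_LEN * hdir
        site = opos + 2.0 * hdir + np.array([0.0, 0.0, 1.5])
        add_residue(part, site, outward=hdir + np.array([0.0, 0.0, 0.7]),
                    active_acceptor_pos=opos)
        names_hb[f"Hb{label_i+1}"] = (donor_n[b], acceptor_o[part])

    # --- donor partners: N–H aimed at the bridge acceptor O
    for label_i, (part, u) in enumerate(
        zip(partners[2:], (np.array([0.8, -0.6, 0.0]), np.array([-0.8, -0.6, 0.0])))
    ):
        npos = o_b + _DA_LEN * u
        hpos = npos - _NH_LEN * u  # points back at o_b: collinear
        site = npos + 2.0 * u + np.array([0.0, 0.0, -1.5])
        add_residue(part, site, outward=u + np.array([0.0, 0.0, -0.7]),
                    active_donor_pos=npos, active_h_pos=[hpos])
        names_hb[f"Hb{label_i+3}"] = (donor_n[part], acceptor_o[b])

    # --- remote residues on a wide ring above the plane
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    for j, res in enumerate(remote):
        ang = 2.0 * np.pi * j / max(len(remote), 1) + 0.3
        site = np.array([11.0 * np.cos(ang), 11.0 * np.sin(ang), 6.0])
        outward = _unit(site - np.array([0.0, 0.0, 6.0]))
        add_residue(res, site + rng.normal(0.0, 0.01, 3), outward)

    # chain bonds between consecutive backbone carbons close the macro-ring
    backbone = [residue_atoms[r][0] for r in range(n_residues)]
    bonds.extend((backbone[r], backbone[(r + 1) % n_residues])
                 for r in range(n_residues))

    closed_arr = np.asarray(closed)
    open_arr = closed_arr.copy()
    for res in range(n_residues):
        if res == b:
            continue
        idxs = residue_atoms[res]
        centroid = closed_arr[idxs].mean(axis=0)
        direction = _unit(centroid - np.array([0.0, -1.3, 0.0]))
        open_arr[idxs] += _OPEN_SHIFT * direction

    topo = Topology(atoms=atoms, bonds=bonds, bridge_residue_id=b,
                    named_hbonds=names_hb)
    return topo, Frame(coordinates=closed_arr), Frame(coordinates=open_arr)


# ---------------------------------------------------------------------------
# Two-state ensembles
# ---------------------------------------------------------------------------


def make_two_state_ensemble(spec: TwoStateSpec) -> ConformerEnsemble:
    """Draw a two-state ensemble with Boltzmann state statistics at t_sim.

    Frame coordinates are the state template plus isotropic Gaussian
    jitter; frame energies are the state energy (0 or ΔE) plus Gaussian
    noise. Deterministic given ``spec.seed``.
    """
    if spec.template_closed.coordinates.shape != spec.template_open.coordinates.shape:
        raise ValueError("closed/open templates differ in atom count")
    if spec.template_closed.coordinates.shape[0] != spec.topology.n_atoms:
        raise ValueError("templates do not match the topology")
    gap = spec.resolved_energy_gap()
    p_closed_sim = boltzmann_p_closed(gap, spec.t_sim)
    ss = np.random.SeedSequence(spec.seed).spawn(3)
    rng_state = np.random.default_rng(ss[0])
    rng_jitter = np.random.default_rng(ss[1])
    rng_energy = np.random.default_rng(ss[2])
    states = rng_state.random(spec.n_frames) < p_closed_sim  # True = closed
    frames: list[Frame] = []
    for closed in states:
        template = spec.template_closed if closed else spec.template_open
        coords = template.coordinates + rng_jitter.normal(
            0.0, spec.jitter_sd, template.coordinates.shape
        )
        energy = (gap if closed else 0.0) + rng_energy.normal(
            0.0, spec.energy_noise_sd
        )
        frames.append(Frame(coordinates=coords, potential_energy=float(energy)))
    return ConformerEnsemble(
        topology=spec.topology,
        frames=frames,
        medium="water",
        simulation_temperature=spec.t_sim,
    )


# ---------------------------------------------------------------------------
# Compound libraries
# ---------------------------------------------------------------------------


def make_library(spec: LibrarySpec) -> tuple[pd.DataFrame, PermeabilityTable]:
    """Descriptor table + permeability table obeying the planted law.

    Descriptors are uniform on ``descriptor_range``;
    log10(P_e / 10⁻⁶ cm·s⁻¹) = slope·x + intercept + N(0, noise_sd).
    """
    ss = np.random.SeedSequence(spec.seed).spawn(2)
    rng_x = np.random.default_rng(ss[0])
    rng_noise = np.random.default_rng(ss[1])
    lo, hi = spec.descriptor_range
    x = rng_x.uniform(lo, hi, spec.n_compounds)
    log_pe = spec.slope * x + spec.intercept + rng_noise.normal(
        0.0, spec.noise_sd, spec.n_compounds
    )
    ids = [f"cmpd{i:03d}" for i in range(spec.n_compounds)]
    descriptors = pd.DataFrame(
        {"compound_id": ids, spec.descriptor_name: x}
    )
    perm = PermeabilityTable(
        data=pd.DataFrame(
            {
                "compound_id": ids,
                "pe": np.power(10.0, log_pe),
                "series_label": spec.series_label,
            }
        )
    )
    return descriptors, perm


def make_born_ion(radius: float, charge: float) -> tuple[Topology, Frame]:
    """Single charged sphere at the origin (Born-ion analytic oracle)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    atom = Atom(
        index=0, element="X", name="ION", residue_id=1, residue_name="ION",
        partial_charge=charge, vdw_radius=radius, is_polar=False,
        is_donor_heavy=False, is_acceptor=False, molecule_tag="solute",
    )
    topo = Topology(atoms=[atom])
    return topo, Frame(coordinates=np.zeros((1, 3)))
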