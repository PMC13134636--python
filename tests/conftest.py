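"""Shared fixtures: toy macrocycle system and random-structure helpers."""

from __future__ import annotations

import numpy as np
import pytest

from macroperm import make_macrocycle_topology
from macroperm.ensemble_io import Atom, Frame, Topology


@pytest.fixture(scope="session")
def macrocycle():
    """(topology, closed_frame, open_frame) of the toy macrobicycle."""
    return make_macrocycle_topology(seed=0)


def random_polar_frame(rng: np.random.Generator, n_heavy: int = 12,
                       box: float = 8.0) -> tuple[Topology, Frame]:
    """Random cluster of C/N/O heavy atoms; most N/O donors carry one H.

    Every heavy atom sits in its own residue, so the intra-residue
    H-bond exclusion rule never triggers and brute-force enumeration over
    (donor, H, acceptor) triples is the exact oracle.
    """
    elements = [str(e) for e in rng.choice(["C", "N", "O"], size=n_heavy,
                                           p=[0.4, 0.3, 0.3])]
    heavy_pos = rng.uniform(0, box, (n_heavy, 3))
    has_h = [e in ("N", "O") and rng.random() < 0.7 for e in elements]
    positions = list(heavy_pos)
    h_index: dict[int, int] = {}
    next_idx = n_heavy
    for i, flag in enumerate(has_h):
        if flag:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            positions.append(heavy_pos[i] + 1.0 * direction)
            h_index[i] = next_idx
            next_idx += 1
    radii = {"C": 1.70, "N": 1.55, "O": 1.52}
    atoms = [
        Atom(index=i, element=e, name=f"{e}{i}", residue_id=i,
             residue_name="RND", vdw_radius=radii[e],
             is_polar=e in ("N", "O"),
             is_donor_heavy=i in h_index,
             is_acceptor=e in ("N", "O"),
             attached_h_indices=(h_index[i],) if i in h_index else (),
             molecule_tag="solute")
        for i, e in enumerate(elements)
    ]
    atoms += [
        Atom(index=h_index[i], element="H", name=f"H{i}", residue_id=i,
             residue_name="RND", vdw_radius=1.20, is_polar=True,
             molecule_tag="solute")
        for i in sorted(h_index)
    ]
    atoms.sort(key=lambda a: a.index)
    return Topology(atoms=atoms), Frame(coordinates=np.asarray(positions))
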