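"""Shared data model and file IO for conformer-ensemble analysis.

The central objects are :class:`Topology` (per-atom chemistry: elements,
partial charges, van der Waals radii, hydrogen-bond donor/acceptor flags,
residue and bridge annotations) and :class:`ConformerEnsemble` (a stack of
coordinate frames of one solute, optionally with per-frame potential
energies and a normalized frame-weight vector).

Ensembles are carried on disk as multi-model PDB files (parsed and written
through ``biotite``) or concatenated XYZ blocks; tabular inputs (per-frame
energies, per-compound permeabilities, frame weights) are RFC-4180 CSV.

Conventions: coordinates in Å, energies in kJ/mol, 0-based atom indices
internally (PDB serial numbers are 1-based on disk only).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "ConformerEnsemble",
    "PermeabilityTable",
    "BONDI_RADII",
    "DEFAULT_SOLVENT_RESIDUES",
    "read_multi_model_pdb",
    "write_multi_model_pdb",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_permeability_csv",
    "read_energy_csv",
    "write_energy_csv",
    "read_weights_csv",
    "write_weights_csv",
]

#: Bondi-style van der Waals radii (Å), used when no per-atom override is given.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Residue names treated as explicit solvent on read.
DEFAULT_SOLVENT_RESIDUES: tuple[str, ...] = ("HOH", "WAT", "SOL", "TIP3", "CL3", "CHL")

# Maximum heavy-atom–hydrogen distance (Å) for inferring covalent attachment
# when no bond list is supplied.
_H_ATTACH_CUTOFF = 1.3


@dataclass(frozen=True)
class Atom:
    """One atom of the solute or solvent with its chemical annotations."""

    index: int
    element: str
    name: str
    residue_id: int
    residue_name: str
    partial_charge: float = 0.0
    vdw_radius: float = 1.70
    is_polar: bool = False
    is_donor_heavy: bool = False
    is_acceptor: bool = False
    attached_h_indices: tuple[int, ...] = ()
    molecule_tag: str = "solute"

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.index}: vdw_radius must be > 0")
        if self.is_donor_heavy and not self.attached_h_indices:
            raise ValueError(
                f"atom {self.index}: donor heavy atom must have attached hydrogens"
            )


@dataclass
class Topology:
    """Ordered atom list plus bonds, bridge annotation, and named H-bond labels.

    ``named_hbonds`` maps a label (e.g. ``"Hb1"``) to a
    ``(donor_heavy_index, acceptor_index)`` pair; these are the specific
    transannular contacts a study tracks by name across an ensemble.
    ``bridge_residue_id`` marks the bridging residue whose side chain links
    the two macrocyclic loops (the candidate hydrogen-bond hub).
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    bridge_residue_id: int | None = None
    named_hbonds: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, atom in enumerate(self.atoms):
            if atom.index != i:
                raise ValueError(f"atom at position {i} has index {atom.index}")
            for h in atom.attached_h_indices:
                if not (0 <= h < n) or self.atoms[h].element != "H":
                    raise ValueError(
                        f"atom {i}: attached_h_indices must reference H atoms"
                    )
        for a, b in self.bonds:
            if a == b:
                raise ValueError(f"self-bond on atom {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"bond ({a}, {b}) references missing atoms")
        for label, (d, a) in self.named_hbonds.items():
            if not self.atoms[d].is_donor_heavy:
                raise ValueError(f"{label}: atom {d} is not a donor heavy atom")
            if not self.atoms[a].is_acceptor:
                raise ValueError(f"{label}: atom {a} is not an acceptor")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def solute_indices(self) -> np.ndarray:
        return np.array(
            [a.index for a in self.atoms if a.molecule_tag == "solute"], dtype=int
        )

    def heavy_solute_indices(self) -> np.ndarray:
        """All non-hydrogen solute atoms (the 'all-heavy-atom' selection)."""
        return np.array(
            [
                a.index
                for a in self.atoms
                if a.molecule_tag == "solute" and a.element != "H"
            ],
            dtype=int,
        )

    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def partial_charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    def residue_of(self, atom_index: int) -> int:
        return self.atoms[atom_index].residue_id


@dataclass
class Frame:
    """One coordinate set (Å) with an optional potential energy (kJ/mol)."""

    coordinates: np.ndarray
    potential_energy: float | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")


@dataclass
class ConformerEnsemble:
    """Frames of one solute in a stated medium, optionally weighted.

    ``weights``, when present, are nonnegative and sum to 1; all ensemble
    averages downstream use them. ``simulation_temperature`` is the
    temperature (K) at which the frames were generated (relevant for
    Boltzmann reweighting to a target temperature).
    """

    topology: Topology
    frames: list[Frame]
    medium: str = "water"
    simulation_temperature: float = 300.0
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_atoms = self.topology.n_atoms
        for k, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n_atoms:
                raise ValueError(
                    f"frame {k}: {fr.coordinates.shape[0]} atoms, expected {n_atoms}"
                )
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.frames),):
                raise ValueError("weights length must equal number of frames")
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1 within 1e-9")
            self.weights = w

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates_array(self) -> np.ndarray:
        """Coordinates as an (n_frames, n_atoms, 3) array."""
        return np.stack([fr.coordinates for fr in self.frames])

    def energies(self) -> np.ndarray | None:
        """Per-frame potential energies, or None if any frame lacks one."""
        es = [fr.potential_energy for fr in self.frames]
        if any(e is None for e in es):
            return None
        return np.array(es, dtype=float)

    def effective_weights(self) -> np.ndarray:
        """Stored weights, or uniform weights when none are attached."""
        if self.weights is not None:
            return self.weights
        n = self.n_frames
        return np.full(n, 1.0 / n)

    def with_weights(self, weights: np.ndarray) -> "ConformerEnsemble":
        return replace(self, weights=np.asarray(weights, dtype=float))


@dataclass
class PermeabilityTable:
    """Per-compound PAMPA permeabilities, P_e in 10⁻⁶ cm/s (all > 0)."""

    data: pd.DataFrame  # columns: compound_id, pe, series_label

    def __post_init__(self) -> None:
        required = {"compound_id", "pe"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"permeability table needs columns {sorted(required)}")
        if "series_label" not in self.data.columns:
            self.data = self.data.assign(series_label="")
        if self.data["compound_id"].duplicated().any():
            dups = self.data.loc[self.data["compound_id"].duplicated(), "compound_id"]
            raise ValueError(f"duplicate compound_id: {sorted(set(dups))}")
        if (self.data["pe"] <= 0).any():
            raise ValueError("pe must be > 0 (drop below-detection rows at load)")

    def log10_pe(self) -> pd.Series:
        return np.log10(self.data.set_index("compound_id")["pe"])


# ---------------------------------------------------------------------------
# Topology construction helpers
# ---------------------------------------------------------------------------


def _infer_attached_hydrogens(
    elements: list[str], coords: np.ndarray, bonds: list[tuple[int, int]]
) -> dict[int, list[int]]:
    """Map heavy-atom index -> attached H indices.

    Uses the bond list when given; otherwise assigns each H to the nearest
    heavy atom within a covalent-distance cutoff on the first frame.
    """
    attached: dict[int, list[int]] = {}
    if bonds:
        for a, b in bonds:
            if elements[a] == "H" and elements[b] != "H":
                attached.setdefault(b, []).append(a)
            elif elements[b] == "H" and elements[a] != "H":
                attached.setdefault(a, []).append(b)
        return attached
    heavy = [i for i, e in enumerate(elements) if e != "H"]
    if not heavy:
        return attached
    heavy_xyz = coords[heavy]
    for i, e in enumerate(elements):
        if e != "H":
            continue
        d = np.linalg.norm(heavy_xyz - coords[i], axis=1)
        j = int(np.argmin(d))
        if d[j] <= _H_ATTACH_CUTOFF:
            attached.setdefault(heavy[j], []).append(i)
    return attached


def build_topology(
    elements: list[str],
    names: list[str],
    residue_ids: list[int],
    residue_names: list[str],
    first_frame: np.ndarray,
    overrides: dict | None = None,
    solvent_residues: tuple[str, ...] = DEFAULT_SOLVENT_RESIDUES,
) -> Topology:
    """Assemble a :class:`Topology`, filling chemistry from defaults + overrides.

    ``overrides`` may contain: ``partial_charges`` (mapping index->e or full
    sequence), ``vdw_radii`` (mapping element->Å or index->Å), ``bonds``,
    ``named_hbonds``, ``bridge_residue_id``, ``donor_indices``,
    ``acceptor_indices``, ``solvent_residues``.
    """
    overrides = overrides or {}
    n = len(elements)
    elements = [e.upper() if len(e) > 1 else e for e in elements]
    solvent_residues = tuple(overrides.get("solvent_residues", solvent_residues))

    radii_override = overrides.get("vdw_radii", {})
    radii = np.empty(n)
    for i, e in enumerate(elements):
        if i in radii_override:
            radii[i] = radii_override[i]
        elif e in radii_override:
            radii[i] = radii_override[e]
        elif e.upper() in BONDI_RADII:
            radii[i] = BONDI_RADII[e.upper()]
        else:
            raise ValueError(
                f"unknown element {e!r} at atom {i}: supply vdw_radii override"
            )

    charges = np.zeros(n)
    q_override = overrides.get("partial_charges")
    if q_override is not None:
        if isinstance(q_override, dict):
            for i, q in q_override.items():
                charges[i] = q
        else:
            charges = np.asarray(q_override, dtype=float)
            if charges.shape != (n,):
                raise ValueError("partial_charges length mismatch")

    bonds = [tuple(b) for b in overrides.get("bonds", [])]
    attached = _infer_attached_hydrogens(elements, first_frame, bonds)

    donor_idx = overrides.get("donor_indices")
    acceptor_idx = overrides.get("acceptor_indices")

    atoms = []
    for i in range(n):
        e = elements[i].upper()
        hs = tuple(sorted(attached.get(i, [])))
        if donor_idx is not None:
            is_donor = i in donor_idx and bool(hs)
        else:
            is_donor = e in ("N", "O", "S") and bool(hs)
        if acceptor_idx is not None:
            is_acceptor = i in acceptor_idx
        else:
            is_acceptor = e in ("N", "O")
        tag = "solvent" if residue_names[i].upper() in solvent_residues else "solute"
        is_polar = e in ("N", "O")
        atoms.append(
            Atom(
                index=i,
                element=e if len(e) == 1 else e.capitalize(),
                name=names[i],
                residue_id=int(residue_ids[i]),
                residue_name=residue_names[i],
                partial_charge=float(charges[i]),
                vdw_radius=float(radii[i]),
                is_polar=is_polar,
                is_donor_heavy=is_donor,
                is_acceptor=is_acceptor,
                attached_h_indices=hs,
                molecule_tag=tag,
            )
        )
    # hydrogens bound to N/O are polar
    polar_h = {
        h for a in atoms if a.element in ("N", "O") for h in a.attached_h_indices
    }
    atoms = [
        replace(a, is_polar=True) if a.index in polar_h else a for a in atoms
    ]
    return Topology(
        atoms=atoms,
        bonds=bonds,
        bridge_residue_id=overrides.get("bridge_residue_id"),
        named_hbonds=dict(overrides.get("named_hbonds", {})),
    )


def topology_overrides_dict(topology: Topology) -> dict:
    """JSON-serializable overrides that reconstruct this topology's chemistry.

    Passing the result (e.g. after a round trip through a JSON file) as
    ``topology_overrides`` to :func:`read_multi_model_pdb` restores partial
    charges, radii, bonds, donor/acceptor flags, named H-bonds, and the
    bridge annotation that the PDB format itself cannot carry.
    """
    return {
        "partial_charges": [a.partial_charge for a in topology.atoms],
        "vdw_radii": {a.index: a.vdw_radius for a in topology.atoms},
        "bonds": [list(b) for b in topology.bonds],
        "named_hbonds": {k: list(v) for k, v in topology.named_hbonds.items()},
        "bridge_residue_id": topology.bridge_residue_id,
        "donor_indices": [a.index for a in topology.atoms if a.is_donor_heavy],
        "acceptor_indices": [a.index for a in topology.atoms if a.is_acceptor],
    }


def _normalize_overrides(raw: dict) -> dict:
    """Coerce JSON-decoded overrides back to the internal conventions."""
    out = dict(raw)
    if "vdw_radii" in out and isinstance(out["vdw_radii"], dict):
        out["vdw_radii"] = {
            (int(k) if str(k).lstrip("-").isdigit() else k): v
            for k, v in out["vdw_radii"].items()
        }
    if "bonds" in out:
        out["bonds"] = [tuple(b) for b in out["bonds"]]
    if "named_hbonds" in out:
        out["named_hbonds"] = {k: tuple(v) for k, v in out["named_hbonds"].items()}
    for key in ("donor_indices", "acceptor_indices"):
        if out.get(key) is not None:
            out[key] = set(out[key])
    return out


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------


def _validate_model_atom_counts(path: str) -> None:
    """Pre-scan MODEL blocks so inconsistent files fail with the model index."""
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = 0
            elif rec == "ENDMDL":
                counts.append(current or 0)
                current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    # coordinates outside MODEL blocks: single implicit model
                    if not counts:
                        counts.append(0)
                    counts[-1] += 1
                else:
                    current += 1
    if len(counts) > 1:
        expected = counts[0]
        for m, c in enumerate(counts[1:], start=2):
            if c != expected:
                raise ValueError(f"model {m}: {c} atoms, expected {expected}")


def read_multi_model_pdb(
    path: str,
    topology_overrides: dict | None = None,
    medium: str = "water",
    simulation_temperature: float = 300.0,
) -> ConformerEnsemble:
    """Read a multi-model PDB file into a :class:`ConformerEnsemble`.

    One frame per MODEL block (or a single frame when no MODEL records are
    present). Atom order must be identical across models; a mismatch raises
    an error naming the model. Charges and radii are filled from
    ``topology_overrides`` or from the default element->radius table.
    """
    _validate_model_atom_counts(path)
    if topology_overrides is not None:
        topology_overrides = _normalize_overrides(topology_overrides)
    pdb = PDBFile.read(path)
    stack = pdb.get_structure(model=None)
    if stack.array_length() == 0:
        raise ValueError(f"{path}: no atoms")
    elements = [e.capitalize() for e in stack.element]
    topo = build_topology(
        elements=elements,
        names=list(stack.atom_name),
        residue_ids=list(stack.res_id),
        residue_names=list(stack.res_name),
        first_frame=np.asarray(stack.coord[0], dtype=float),
        overrides=topology_overrides,
    )
    frames = [Frame(coordinates=np.asarray(c, dtype=float)) for c in stack.coord]
    return ConformerEnsemble(
        topology=topo,
        frames=frames,
        medium=medium,
        simulation_temperature=simulation_temperature,
    )


def write_multi_model_pdb(ensemble: ConformerEnsemble, path: str) -> None:
    """Write an ensemble as a multi-model PDB file (via biotite)."""
    topo = ensemble.topology
    n = topo.n_atoms
    array = struc.AtomArray(n)
    array.coord = np.zeros((n, 3), dtype=np.float32)
    for i, atom in enumerate(topo.atoms):
        array.atom_name[i] = atom.name[:4]
        array.element[i] = atom.element.upper()
        array.res_id[i] = atom.residue_id
        array.res_name[i] = atom.residue_name[:3]
        array.hetero[i] = True
        array.chain_id[i] = "A"
    coords = ensemble.coordinates_array().astype(np.float32)
    stack = struc.stack([array] * ensemble.n_frames)
    stack.coord = coords
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


# ---------------------------------------------------------------------------
# XYZ trajectory
# ---------------------------------------------------------------------------

_ENERGY_RE = re.compile(r"E=\s*([-+]?\d+\.?\d*(?:[eE][-+]?\d+)?)")


def read_xyz_trajectory(path: str, topology: Topology, medium: str = "water",
                        simulation_temperature: float = 300.0) -> ConformerEnsemble:
    """Read concatenated XYZ blocks; `E=<float>` comments become frame energies.

    Energies must be present on every frame or on none (mixed presence is an
    error). The atom count in every block header must match the topology.
    """
    frames: list[Frame] = []
    energies: list[float | None] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos = 0
    block = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(f"block {block}: bad atom-count header") from exc
        if count != topology.n_atoms:
            raise ValueError(
                f"block {block}: {count} atoms, expected {topology.n_atoms}"
            )
        comment = lines[pos + 1]
        m = _ENERGY_RE.search(comment)
        energies.append(float(m.group(1)) if m else None)
        coords = np.empty((count, 3))
        for i in range(count):
            parts = lines[pos + 2 + i].split()
            coords[i] = [float(x) for x in parts[1:4]]
        frames.append(Frame(coordinates=coords))
        pos += 2 + count
        block += 1
    if not frames:
        raise ValueError(f"{path}: empty trajectory")
    have = [e is not None for e in energies]
    if any(have) and not all(have):
        raise ValueError("mixed energy presence across XYZ frames")
    if all(have):
        for fr, e in zip(frames, energies):
            fr.potential_energy = e
    return ConformerEnsemble(
        topology=topology,
        frames=frames,
        medium=medium,
        simulation_temperature=simulation_temperature,
    )


def write_xyz_trajectory(ensemble: ConformerEnsemble, path: str) -> None:
    elements = [a.element for a in ensemble.topology.atoms]
    with open(path, "w") as fh:
        for fr in ensemble.frames:
            fh.write(f"{len(elements)}\n")
            if fr.potential_energy is not None:
                fh.write(f"E={fr.potential_energy:.10g}\n")
            else:
                fh.write("\n")
            for e, (x, y, z) in zip(elements, fr.coordinates):
                fh.write(f"{e} {x:.8f} {y:.8f} {z:.8f}\n")


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------


def read_permeability_csv(path: str) -> PermeabilityTable:
    """Load a compound permeability table; drops pe<=0 rows with a warning."""
    df = pd.read_csv(path)
    if not {"compound_id", "pe"}.issubset(df.columns):
        raise ValueError("permeability CSV needs compound_id and pe columns")
    bad = df["pe"] <= 0
    if bad.any():
        dropped = df.loc[bad, "compound_id"].tolist()
        warnings.warn(
            f"dropping {int(bad.sum())} below-detection rows (pe <= 0): {dropped}",
            stacklevel=2,
        )
        df = df.loc[~bad].reset_index(drop=True)
    df["compound_id"] = df["compound_id"].astype(str)
    return PermeabilityTable(data=df)


def read_energy_csv(path: str) -> np.ndarray:
    """Per-frame energies (kJ/mol) from a (frame_index, energy) CSV."""
    df = pd.read_csv(path)
    col = "energy_kj_mol" if "energy_kj_mol" in df.columns else "energy"
    if col not in df.columns or "frame_index" not in df.columns:
        raise ValueError("energy CSV needs frame_index and energy columns")
    df = df.sort_values("frame_index")
    if not np.array_equal(df["frame_index"].to_numpy(), np.arange(len(df))):
        raise ValueError("frame_index must be contiguous from 0")
    return df[col].to_numpy(dtype=float)


def write_energy_csv(energies: np.ndarray, path: str) -> None:
    pd.DataFrame(
        {"frame_index": np.arange(len(energies)), "energy_kj_mol": energies}
    ).to_csv(path, index=False)


def read_weights_csv(path: str) -> np.ndarray:
    df = pd.read_csv(path).sort_values("frame_index")
    return df["weight"].to_numpy(dtype=float)


def write_weights_csv(weights: np.ndarray, path: str) -> None:
    pd.DataFrame(
        {"frame_index": np.arange(len(weights)), "weight": weights}
    ).to_csv(path, index=False)
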