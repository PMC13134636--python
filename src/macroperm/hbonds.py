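"""Hydrogen-bond detection, weighted frequencies, and hub analysis.

A hydrogen bond is a donor-heavy/hydrogen/acceptor triple satisfying a
geometric rule: donor–acceptor distance at most ``max_da_distance``
(default 3.5 Å) and donor–H–acceptor angle at least ``min_dha_angle``
(default 135°). Trivial contacts inside one functional group are excluded:
a donor and acceptor in the same residue count only when separated by at
least 3 covalent bonds (pairs with no bond path available are excluded).

Frequencies are weighted fractions of frames containing a given
donor–acceptor pair, so a reweighted ensemble yields room-temperature
bond populations directly. The hub analysis asks whether a residue — the
bridging residue of a macrobicycle — simultaneously donates and accepts
hydrogen bonds to several partner residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ensemble_io import ConformerEnsemble, Frame, Topology

__all__ = [
    "HBondCriteria",
    "HBondEvent",
    "HBondFrequencyTable",
    "HubSummary",
    "detect_hbonds",
    "hbond_frequencies",
    "hub_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 3.5  # Å
    min_dha_angle: float = 135.0  # degrees

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be > 0")
        if not (0 < self.min_dha_angle <= 180):
            raise ValueError("min_dha_angle must be in (0, 180]")


@dataclass(frozen=True)
class HBondEvent:
    donor_heavy: int
    hydrogen: int
    acceptor: int
    da_distance: float
    dha_angle: float
    kind: str  # "intramolecular" | "solute-solvent"


@dataclass
class HBondFrequencyTable:
    """Weighted bond frequencies keyed by (donor_heavy, acceptor) pair."""

    pair_frequencies: dict[tuple[int, int], float]
    named_frequencies: dict[str, float]
    total_intramolecular: float   # weighted fraction of frames with >=1 IMHB
    total_solute_solvent: float   # weighted fraction of frames with >=1 solute-solvent bond
    criteria: HBondCriteria = field(default_factory=HBondCriteria)


@dataclass
class HubSummary:
    residue_id: int
    partner_residues: set[int]
    degree: int
    donor_and_acceptor: bool
    threshold: float


def _bond_separations(topology: Topology) -> dict[int, dict[int, int]]:
    """All-pairs shortest bond-path lengths via BFS (small molecules only)."""
    adj: dict[int, list[int]] = {}
    for a, b in topology.bonds:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    seps: dict[int, dict[int, int]] = {}
    for start in adj:
        dist = {start: 0}
        queue = [start]
        while queue:
            nxt = []
            for u in queue:
                for v in adj.get(u, []):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            queue = nxt
        seps[start] = dist
    return seps


def _pair_allowed(topology: Topology, seps, donor: int, acceptor: int) -> bool:
    da = topology.atoms[donor]
    aa = topology.atoms[acceptor]
    if da.residue_id != aa.residue_id:
        return True
    # same residue: require >= 3 covalent bonds' separation; pairs with no
    # bond path on record are excluded (separation unverifiable)
    sep = seps.get(donor, {}).get(acceptor)
    return sep is not None and sep >= 3


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBondEvent]:
    """All hydrogen bonds of one frame under the geometric criteria.

    Emits one event per (donor-heavy, H, acceptor) triple passing both the
    distance and angle cutoffs. Bonds within solvent are ignored; a bond
    with exactly one solvent partner is kind ``"solute-solvent"``.
    """
    xyz = frame.coordinates
    seps = _bond_separations(topology)
    donors = [a for a in topology.atoms if a.is_donor_heavy and a.attached_h_indices]
    skipped = [a.index for a in topology.atoms if a.is_donor_heavy and not a.attached_h_indices]
    if skipped:
        logger.warning("donors with no attached H skipped: %s", skipped)
    acceptors = [a for a in topology.atoms if a.is_acceptor]
    events: list[HBondEvent] = []
    for don in donors:
        for acc in acceptors:
            if acc.index == don.index:
                continue
            if don.molecule_tag == "solvent" and acc.molecule_tag == "solvent":
                continue
            if not _pair_allowed(topology, seps, don.index, acc.index):
                continue
            d_da = float(np.linalg.norm(xyz[don.index] - xyz[acc.index]))
            if d_da > criteria.max_da_distance:
                continue
            for h in don.attached_h_indices:
                v1 = xyz[don.index] - xyz[h]
                v2 = xyz[acc.index] - xyz[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle < criteria.min_dha_angle:
                    continue
                kind = (
                    "intramolecular"
                    if don.molecule_tag == "solute" and acc.molecule_tag == "solute"
                    else "solute-solvent"
                )
                events.append(
                    HBondEvent(
                        donor_heavy=don.index,
                        hydrogen=h,
                        acceptor=acc.index,
                        da_distance=d_da,
                        dha_angle=angle,
                        kind=kind,
                    )
                )
    return events


def hbond_frequencies(
    ensemble: ConformerEnsemble,
    criteria: HBondCriteria = HBondCriteria(),
    weights: np.ndarray | None = None,
) -> HBondFrequencyTable:
    """Weighted per-pair bond frequencies over an ensemble.

    The frequency of a (donor, acceptor) pair is the summed weight of
    frames in which at least one H of the donor bonds the acceptor, hence
    lies in [0, 1]. Named bonds from the topology are always reported,
    with frequency 0 when never observed.
    """
    if weights is None:
        weights = ensemble.effective_weights()
    w = np.asarray(weights, dtype=float)
    if w.shape != (ensemble.n_frames,):
        raise ValueError("weights length mismatch")
    pair_freq: dict[tuple[int, int], float] = {}
    total_intra = 0.0
    total_solv = 0.0
    for k, fr in enumerate(ensemble.frames):
        events = detect_hbonds(fr, ensemble.topology, criteria)
        pairs = {(e.donor_heavy, e.acceptor) for e in events}
        for p in pairs:
            pair_freq[p] = pair_freq.get(p, 0.0) + w[k]
        if any(e.kind == "intramolecular" for e in events):
            total_intra += w[k]
        if any(e.kind == "solute-solvent" for e in events):
            total_solv += w[k]
    named = {
        label: pair_freq.get(tuple(pair), 0.0)
        for label, pair in ensemble.topology.named_hbonds.items()
    }
    return HBondFrequencyTable(
        pair_frequencies=pair_freq,
        named_frequencies=named,
        total_intramolecular=total_intra,
        total_solute_solvent=total_solv,
        criteria=criteria,
    )


def hub_summary(
    frequency_table: HBondFrequencyTable,
    topology: Topology,
    residue_id: int | None = None,
    threshold: float = 0.1,
) -> HubSummary:
    """Connectivity of one residue in the intramolecular H-bond network.

    Partners are residues sharing at least one donor–acceptor pair with
    frequency >= threshold; the residue is a donor-and-acceptor hub when
    it appears on the donor side of one such pair and the acceptor side of
    another.
    """
    if residue_id is None:
        residue_id = topology.bridge_residue_id
    if residue_id is None:
        raise ValueError("no residue_id given and topology has no bridge residue")
    if not any(a.residue_id == residue_id for a in topology.atoms):
        raise ValueError(f"residue {residue_id} not in topology")
    partners: set[int] = set()
    donates = accepts = False
    for (d, a), freq in frequency_table.pair_frequencies.items():
        if freq < threshold:
            continue
        rd = topology.residue_of(d)
        ra = topology.residue_of(a)
        if rd == residue_id and ra != residue_id:
            partners.add(ra)
            donates = True
        elif ra == residue_id and rd != residue_id:
            partners.add(rd)
            accepts = True
    return HubSummary(
        residue_id=residue_id,
        partner_residues=partners,
        degree=len(partners),
        donor_and_acceptor=donates and accepts,
        threshold=threshold,
    )
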