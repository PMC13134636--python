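"""Conformer clustering, open/closed macrostate populations, and ΔG_conf.

Chameleonic macrocycles populate an "open" macrostate (polar groups
solvent-exposed) in water and a "closed", internally hydrogen-bonded
macrostate in nonpolar media. The conformational free-energy penalty of
shifting the aqueous equilibrium to the membrane-permeating closed state
is

    ΔG_conf = -R·T·ln(P_closed / P_open),   R = 8.314 J/(mol·K)

positive when closed is the minority state in water.

Clustering follows the Daura (quality-threshold) greedy scheme on
all-heavy-atom Kabsch RMSD: the frame with the largest weighted neighbour
count within the cutoff seeds the top cluster, its neighbours are
removed, and the rule repeats. Frames can be classified open/closed either
by RMSD to a closed reference structure (typically the top-cluster medoid
of the nonpolar-medium ensemble) or by counting named intramolecular
hydrogen bonds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ensemble_io import ConformerEnsemble
from .hbonds import HBondCriteria, detect_hbonds
from .surface import kabsch_rmsd

__all__ = [
    "GAS_CONSTANT_KJ",
    "ClusterAssignment",
    "MacrostateSplit",
    "pairwise_heavy_rmsd",
    "cluster_ensemble",
    "classify_open_closed",
    "delta_g_conf",
]

logger = logging.getLogger(__name__)

#: Ideal gas constant in kJ/(mol·K).
GAS_CONSTANT_KJ = 8.314e-3


@dataclass
class ClusterAssignment:
    frame_cluster: np.ndarray        # cluster id per frame (0 = most populated)
    populations: np.ndarray          # weighted population per cluster
    representatives: np.ndarray      # medoid frame index per cluster
    rmsd_cutoff: float

    def __post_init__(self) -> None:
        if abs(self.populations.sum() - 1.0) > 1e-9:
            raise ValueError("cluster populations must sum to 1")


@dataclass
class MacrostateSplit:
    p_open: float
    p_closed: float
    p_other: float
    temperature: float
    delta_g_conf: float | None
    classification_mode: str

    def __post_init__(self) -> None:
        if abs(self.p_open + self.p_closed + self.p_other - 1.0) > 1e-9:
            raise ValueError("macrostate populations must sum to 1")


def pairwise_heavy_rmsd(ensemble: ConformerEnsemble) -> np.ndarray:
    """Symmetric all-heavy-atom Kabsch RMSD matrix over all frame pairs."""
    sel = ensemble.topology.heavy_solute_indices()
    coords = ensemble.coordinates_array()[:, sel, :]
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch_rmsd(coords[i], coords[j])
    return mat


def cluster_ensemble(
    ensemble: ConformerEnsemble,
    weights: np.ndarray | None = None,
    rmsd_cutoff: float = 1.0,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterAssignment:
    """Greedy quality-threshold clustering on all-heavy-atom RMSD.

    Deterministic: the next cluster center is the unassigned frame with
    the largest weighted neighbour count within the cutoff, ties broken by
    lowest frame index; clusters are renumbered by descending population.
    The representative of each cluster is its weighted medoid (smallest
    weighted mean RMSD to the other members).
    """
    if ensemble.n_frames < 1:
        raise ValueError("need at least one frame")
    if rmsd_cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if weights is None:
        weights = ensemble.effective_weights()
    w = np.asarray(weights, dtype=float)
    mat = pairwise_heavy_rmsd(ensemble) if rmsd_matrix is None else rmsd_matrix
    n = ensemble.n_frames
    unassigned = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    reps: list[int] = []
    pops: list[float] = []
    cluster = 0
    neigh = mat <= rmsd_cutoff
    while unassigned.any():
        counts = (neigh & unassigned[None, :]).astype(float) @ w
        counts[~unassigned] = -np.inf
        center = int(np.argmax(counts))  # np.argmax returns the lowest tied index
        members = np.flatnonzero(neigh[center] & unassigned)
        labels[members] = cluster
        unassigned[members] = False
        # weighted medoid of the members
        sub = mat[np.ix_(members, members)]
        medoid = members[int(np.argmin(sub @ w[members]))]
        reps.append(int(medoid))
        pops.append(float(w[members].sum()))
        cluster += 1
    order = np.argsort(-np.asarray(pops), kind="stable")
    relabel = np.empty(cluster, dtype=int)
    relabel[order] = np.arange(cluster)
    return ClusterAssignment(
        frame_cluster=relabel[labels],
        populations=np.asarray(pops)[order] / w.sum(),
        representatives=np.asarray(reps, dtype=int)[order],
        rmsd_cutoff=rmsd_cutoff,
    )


def classify_open_closed(
    ensemble: ConformerEnsemble,
    weights: np.ndarray | None = None,
    mode: str = "rmsd-to-closed-reference",
    closed_reference: np.ndarray | None = None,
    open_reference: np.ndarray | None = None,
    imhb_labels: list[str] | None = None,
    min_imhb_count: int = 3,
    cutoff: float = 1.5,
    temperature: float = 300.0,
    criteria: HBondCriteria = HBondCriteria(),
    regularize: bool = False,
) -> MacrostateSplit:
    """Split an ensemble into open/closed macrostates and evaluate ΔG_conf.

    mode "rmsd-to-closed-reference": a frame is closed when its
    all-heavy-atom RMSD to ``closed_reference`` is <= ``cutoff`` (Å); with
    an additional ``open_reference``, frames near neither reference count
    as "other" (frames within cutoff of both are assigned closed and
    logged). mode "imhb-count": a frame is closed when at least
    ``min_imhb_count`` of the named intramolecular H-bonds are present.

    Populations are weighted sums; ΔG_conf is evaluated at ``temperature``
    when both populations are positive (optionally after adding the
    regularization pseudo-weight; see :func:`delta_g_conf`).
    """
    if weights is None:
        weights = ensemble.effective_weights()
    w = np.asarray(weights, dtype=float)
    topo = ensemble.topology
    n = ensemble.n_frames
    sel = topo.heavy_solute_indices()
    closed_mask = np.zeros(n, dtype=bool)
    other_mask = np.zeros(n, dtype=bool)
    if mode == "rmsd-to-closed-reference":
        if closed_reference is None:
            raise ValueError("rmsd mode requires a closed_reference coordinate set")
        both = 0
        for k, fr in enumerate(ensemble.frames):
            d_closed = kabsch_rmsd(fr.coordinates[sel], closed_reference[sel])
            if d_closed <= cutoff:
                closed_mask[k] = True
                if open_reference is not None:
                    if kabsch_rmsd(fr.coordinates[sel], open_reference[sel]) <= cutoff:
                        both += 1  # ambiguous: assigned closed
            elif open_reference is not None:
                d_open = kabsch_rmsd(fr.coordinates[sel], open_reference[sel])
                if d_open > cutoff:
                    other_mask[k] = True
        if both:
            logger.warning("%d frames within cutoff of both references; "
                           "assigned closed", both)
    elif mode == "imhb-count":
        if not topo.named_hbonds:
            raise ValueError("imhb-count mode requires named H-bonds on the topology")
        labels = imhb_labels or list(topo.named_hbonds)
        watched = {tuple(topo.named_hbonds[lbl]) for lbl in labels}
        for k, fr in enumerate(ensemble.frames):
            pairs = {(e.donor_heavy, e.acceptor)
                     for e in detect_hbonds(fr, topo, criteria)}
            if len(watched & pairs) >= min_imhb_count:
                closed_mask[k] = True
    else:
        raise ValueError(f"unknown classification mode {mode!r}")
    p_closed = float(w[closed_mask].sum())
    p_other = float(w[other_mask].sum())
    p_open = max(0.0, 1.0 - p_closed - p_other)
    dg = None
    if (p_closed > 0 and p_open > 0) or regularize:
        dg = delta_g_conf(p_closed, p_open, temperature,
                          regularize=regularize, n_frames=n)
    return MacrostateSplit(
        p_open=p_open,
        p_closed=p_closed,
        p_other=p_other,
        temperature=temperature,
        delta_g_conf=dg,
        classification_mode=mode,
    )


def delta_g_conf(
    p_closed: float,
    p_open: float,
    temperature: float = 300.0,
    regularize: bool = False,
    n_frames: int | None = None,
) -> float:
    """Conformational free-energy penalty -RT·ln(P_closed/P_open), kJ/mol.

    Zero populations make the log ratio undefined; with ``regularize`` a
    pseudo-weight ε = 1/(n_frames + 2) is added to both populations (the
    Laplace rule), which is logged.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if p_closed <= 0 or p_open <= 0:
        if not regularize:
            raise ValueError(
                "p_closed and p_open must be > 0; pass regularize=True to add "
                "the pseudo-weight 1/(n+2)"
            )
        if n_frames is None:
            raise ValueError("regularization requires n_frames")
        eps = 1.0 / (n_frames + 2)
        logger.info("regularizing populations with pseudo-weight %.3g", eps)
        p_closed += eps
        p_open += eps
    return float(-GAS_CONSTANT_KJ * temperature * np.log(p_closed / p_open))
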