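"""Geometric ensemble descriptors: SASA, 3D polar surface area, Kabsch RMSD.

The solvent-accessible surface area (SASA) is computed with the
Shrake–Rupley algorithm on a deterministic golden-spiral point set, so
descriptor values are exactly reproducible run to run. The 3D polar
surface area (3D_PSA) is the per-atom SASA summed over a polar-atom set
(by default N, O, and hydrogens bonded to N/O; sulfur and fluorine can be
included by policy). Ensemble descriptors are weighted means over frames,
using the reweighting weights when attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble_io import ConformerEnsemble, Frame, Topology

__all__ = [
    "PolarPolicy",
    "SurfaceResult",
    "golden_spiral_points",
    "shrake_rupley",
    "psa_3d",
    "polar_atom_indices",
    "ensemble_average",
    "kabsch_rmsd",
    "ensemble_surface_descriptors",
]


@dataclass(frozen=True)
class PolarPolicy:
    """Which atoms count as polar for 3D_PSA.

    Default follows classical polar-surface-area conventions: nitrogen,
    oxygen, and hydrogens attached to them. ``include_s``/``include_f``
    extend the set; fluorine-rich scaffolds (e.g. a fluorocrown bridge)
    would otherwise have their PSA dominated by fluorine, so the choice is
    explicit and recorded in reports.
    """

    include_s: bool = False
    include_f: bool = False

    def label(self) -> str:
        extra = ("S" if self.include_s else "") + ("F" if self.include_f else "")
        return "NO+H" + (f"+{extra}" if extra else "")


@dataclass
class SurfaceResult:
    """Per-atom accessible areas (Å²) for the solute atoms of one frame."""

    atom_indices: np.ndarray   # topology indices the areas refer to
    per_atom_area: np.ndarray  # Å², aligned with atom_indices
    total_sasa: float
    psa_3d: float
    probe_radius: float
    n_sphere_points: int


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere point set (Fibonacci lattice)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def polar_atom_indices(topology: Topology, policy: PolarPolicy = PolarPolicy()) -> set[int]:
    """Solute atoms counted as polar under the policy."""
    elems = {"N", "O"}
    if policy.include_s:
        elems.add("S")
    if policy.include_f:
        elems.add("F")
    polar: set[int] = set()
    for a in topology.atoms:
        if a.molecule_tag != "solute":
            continue
        if a.element in elems:
            polar.add(a.index)
            for h in a.attached_h_indices:
                if a.element in ("N", "O"):
                    polar.add(h)
    return polar


def shrake_rupley(
    frame: Frame,
    topology: Topology,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    polar_policy: PolarPolicy = PolarPolicy(),
) -> SurfaceResult:
    """Shrake–Rupley SASA of the solute atoms of one frame.

    Each atom's accessible sphere (radius = vdW + probe) is tiled with the
    golden-spiral point set; the accessible fraction is the share of points
    not buried inside any neighbour's accessible sphere.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_sphere_points < 32:
        raise ValueError("n_sphere_points must be >= 32")
    idx = topology.solute_indices()
    xyz = frame.coordinates[idx]
    radii = topology.vdw_radii()[idx] + probe_radius
    n = len(idx)
    # identical coordinates make the buried/exposed split ill-defined
    if n > 1:
        d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if np.min(d2) < 1e-12:
            i, j = np.unravel_index(np.argmin(d2), d2.shape)
            raise ValueError(f"atoms {idx[i]} and {idx[j]} have identical coordinates")
    unit = golden_spiral_points(n_sphere_points)
    areas = np.empty(n)
    for i in range(n):
        pts = xyz[i] + radii[i] * unit
        if n > 1:
            neighbors = np.flatnonzero(
                (d2[i] < (radii[i] + radii) ** 2) & (np.arange(n) != i)
            )
        else:
            neighbors = np.array([], dtype=int)
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            accessible &= (
                np.sum((pts - xyz[j]) ** 2, axis=1) > radii[j] ** 2
            )
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    polar = polar_atom_indices(topology, polar_policy)
    psa = float(areas[[k for k, a in enumerate(idx) if a in polar]].sum()) if n else 0.0
    return SurfaceResult(
        atom_indices=idx,
        per_atom_area=areas,
        total_sasa=float(areas.sum()),
        psa_3d=psa,
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
    )


def psa_3d(
    surface_result: SurfaceResult,
    topology: Topology,
    polar_policy: PolarPolicy = PolarPolicy(),
) -> float:
    """3D polar surface area: per-atom SASA summed over the polar set."""
    polar = polar_atom_indices(topology, polar_policy)
    mask = [k for k, a in enumerate(surface_result.atom_indices) if a in polar]
    return float(surface_result.per_atom_area[mask].sum())


def ensemble_average(values: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted ensemble mean Σ wᵢ·vᵢ (uniform weights when none given)."""
    v = np.asarray(values, dtype=float)
    if weights is None:
        return float(v.mean())
    w = np.asarray(weights, dtype=float)
    if w.shape != v.shape:
        raise ValueError("values and weights length mismatch")
    return float(np.sum(w * v))


def kabsch_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    atom_selection: np.ndarray | None = None,
) -> float:
    """Minimal RMSD (Å) between two coordinate sets after optimal rigid fit.

    Centers both selections, finds the proper rotation minimizing the
    residual (Kabsch superposition via SVD), and returns the RMSD. The
    selections must contain at least 3 non-collinear atoms.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if atom_selection is not None:
        a = a[atom_selection]
        b = b[atom_selection]
    if a.shape != b.shape:
        raise ValueError("coordinate selections differ in shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a, b)
    # recompute the residual directly: the rssd reported by align_vectors
    # loses precision to cancellation for near-congruent sets
    diff = a - rot.apply(b)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def ensemble_surface_descriptors(
    ensemble: ConformerEnsemble,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    polar_policy: PolarPolicy = PolarPolicy(),
) -> dict:
    """Per-frame and weighted-mean SASA / 3D_PSA for an ensemble."""
    sasa = np.empty(ensemble.n_frames)
    psa = np.empty(ensemble.n_frames)
    for k, fr in enumerate(ensemble.frames):
        res = shrake_rupley(fr, ensemble.topology, probe_radius, n_sphere_points,
                            polar_policy)
        sasa[k] = res.total_sasa
        psa[k] = res.psa_3d
    w = ensemble.effective_weights()
    return {
        "per_frame_sasa": sasa,
        "per_frame_psa_3d": psa,
        "sasa_mean": ensemble_average(sasa, w),
        "psa_3d_mean": ensemble_average(psa, w),
        "probe_radius": probe_radius,
        "n_sphere_points": n_sphere_points,
        "polar_policy": polar_policy.label(),
    }
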