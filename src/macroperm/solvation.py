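"""Implicit-solvation free energies and the water→chloroform transfer penalty.

A generalized-Born / surface-area (GB/SA) model:

* polar term: GB polarization energy with the canonical pair function
  f_GB(r, Ri, Rj) = sqrt(r² + Ri·Rj·exp(-r²/(4·Ri·Rj))) and prefactor
  -½·332.06·(1/ε_in - 1/ε_out) kcal·Å/(mol·e²); effective Born radii from
  Hawkins–Cramer–Truhlar pairwise descreening with the
  Onufriev–Bashford–Case (OBC-II) tanh rescaling;
* nonpolar term: γ·SASA + b with γ = 0.00542 kcal/(mol·Å²), b = 0.92
  kcal/mol.

The transfer penalty ΔG_loss = ⟨G_solv(chloroform)⟩ - ⟨G_solv(water)⟩ is
positive for molecules better solvated by water; by default the nonpolar
term uses the same γ/b in both solvents so ΔG_loss isolates the polar
desolvation physics. Absolute solvation energies from this desk-scale
model should not be compared with force-field or experimental values;
the intended use is relative, across a congeneric compound series.

All energies are kcal/mol; 1 kcal = 4.184 kJ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble_io import ConformerEnsemble, Frame, Topology
from .surface import PolarPolicy, ensemble_average, shrake_rupley

__all__ = [
    "COULOMB_KCAL", "KCAL_TO_KJ", "SolventModel", "WATER", "CHLOROFORM",
    "SolvationResult", "effective_born_radii", "gb_polarization_energy",
    "solvation_free_energy", "delta_g_loss",
]

#: Coulomb constant, kcal·Å/(mol·e²).
COULOMB_KCAL = 332.06
KCAL_TO_KJ = 4.184

# OBC-II rescaling coefficients and HCT screening factor
_OBC_ALPHA, _OBC_BETA, _OBC_GAMMA = 1.0, 0.8, 4.85
_DEFAULT_SCREEN = 0.8
_DEFAULT_OFFSET = 0.09  # Å


@dataclass(frozen=True)
class SolventModel:
    """Dielectric continuum plus linear surface-tension nonpolar term."""

    name: str
    dielectric: float
    surface_tension_gamma: float = 0.00542  # kcal/(mol·Å²)
    surface_offset_b: float = 0.92          # kcal/mol

    def __post_init__(self) -> None:
        if self.dielectric < 1:
            raise ValueError("dielectric must be >= 1")
        if self.surface_tension_gamma < 0:
            raise ValueError("surface tension must be >= 0")


WATER = SolventModel("water", 78.5)
CHLOROFORM = SolventModel("chloroform", 4.81)


@dataclass
class SolvationResult:
    """Per-frame and ensemble-mean GB/SA solvation free energies (kcal/mol)."""

    solvent: str
    per_frame_g_polar: np.ndarray
    per_frame_g_nonpolar: np.ndarray
    per_frame_g_solv: np.ndarray = field(init=False)
    g_polar_mean: float = field(init=False)
    g_nonpolar_mean: float = field(init=False)
    g_solv_mean: float = field(init=False)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.per_frame_g_solv = self.per_frame_g_polar + self.per_frame_g_nonpolar
        w = self.weights
        self.g_polar_mean = ensemble_average(self.per_frame_g_polar, w)
        self.g_nonpolar_mean = ensemble_average(self.per_frame_g_nonpolar, w)
        self.g_solv_mean = ensemble_average(self.per_frame_g_solv, w)


def _hct_integral(r: np.ndarray, s: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """HCT descreening integral H(r, s; ρ) for each pair.

    r: donor–scaler distance; s: scaled radius of the descreening atom;
    rho: offset-reduced intrinsic radius of the descreened atom. Vectorized
    over arrays of equal shape. Returns 0 where the descreening sphere lies
    entirely inside the atom's own radius (r + s <= ρ).
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    rho = np.asarray(rho, dtype=float)
    out = np.zeros(np.broadcast(r, s, rho).shape)
    active = r + s > rho
    if not np.any(active):
        return out
    r_, s_, rho_ = np.broadcast_arrays(r, s, rho)
    r_, s_, rho_ = r_[active], s_[active], rho_[active]
    u = r_ + s_
    low = np.maximum(np.abs(r_ - s_), rho_)
    term = 0.5 * (
        1.0 / low
        - 1.0 / u
        + 0.25 * (r_ - s_**2 / r_) * (1.0 / u**2 - 1.0 / low**2)
        + 0.5 / r_ * np.log(low / u)
    )
    # atom center engulfed by the descreening sphere
    inside = (s_ - r_) > rho_
    term[inside] += 2.0 * (1.0 / rho_[inside] - 1.0 / low[inside])
    out[active] = term
    return out


def effective_born_radii(
    frame: Frame,
    topology: Topology,
    intrinsic_radii: np.ndarray | None = None,
    offset: float = _DEFAULT_OFFSET,
    screen: float = _DEFAULT_SCREEN,
) -> np.ndarray:
    """OBC-style effective Born radii (Å) for the solute atoms.

    An isolated atom's effective radius is its intrinsic radius minus the
    offset; burial by neighbours (pairwise HCT descreening, uniform
    screening factor) only increases it. The OBC tanh rescaling keeps the
    radii finite and monotone in the descreening sum.
    """
    idx = topology.solute_indices()
    xyz = frame.coordinates[idx]
    if intrinsic_radii is None:
        intrinsic_radii = topology.vdw_radii()[idx]
    rho_full = np.asarray(intrinsic_radii, dtype=float)
    if rho_full.shape != (len(idx),):
        raise ValueError("intrinsic_radii length must match solute atom count")
    if np.any(rho_full <= offset):
        bad = int(np.flatnonzero(rho_full <= offset)[0])
        raise ValueError(f"atom {idx[bad]}: intrinsic radius <= offset {offset}")
    rho = rho_full - offset
    n = len(idx)
    if n == 1:
        return rho.copy()
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    s = screen * rho  # scaled descreening radii
    integral = _hct_integral(d, s[None, :], rho[:, None])
    np.fill_diagonal(integral, 0.0)
    i_sum = integral.sum(axis=1)
    psi = i_sum * rho
    inv_r = 1.0 / rho - np.tanh(
        _OBC_ALPHA * psi - _OBC_BETA * psi**2 + _OBC_GAMMA * psi**3
    ) / rho_full
    return 1.0 / inv_r


def gb_polarization_energy(
    frame: Frame,
    charges: np.ndarray,
    born_radii: np.ndarray,
    eps_in: float = 1.0,
    eps_out: float = 78.5,
    solute_indices: np.ndarray | None = None,
) -> float:
    """Still-style generalized-Born polarization energy (kcal/mol).

    E = -½·332.06·(1/ε_in - 1/ε_out)·Σ_ij q_i q_j / f_GB(r_ij, R_i, R_j),
    the double sum running over all ordered pairs including i=j (self terms
    reproduce the Born ion). Zero when all charges vanish or ε_out = ε_in.
    """
    if not (1.0 <= eps_in <= eps_out):
        raise ValueError("need eps_out >= eps_in >= 1")
    q = np.asarray(charges, dtype=float)
    r_born = np.asarray(born_radii, dtype=float)
    if np.any(r_born <= 0):
        raise ValueError("Born radii must be > 0")
    xyz = frame.coordinates if solute_indices is None else frame.coordinates[solute_indices]
    if not (len(q) == len(r_born) == len(xyz)):
        raise ValueError("charges, born_radii, coordinates length mismatch")
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
    rr = r_born[:, None] * r_born[None, :]
    f = np.sqrt(d2 + rr * np.exp(-d2 / (4.0 * rr)))
    prefactor = -0.5 * COULOMB_KCAL * (1.0 / eps_in - 1.0 / eps_out)
    return float(prefactor * np.sum(q[:, None] * q[None, :] / f))


def solvation_free_energy(
    ensemble: ConformerEnsemble,
    solvent_model: SolventModel,
    weights: np.ndarray | None = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    eps_in: float = 1.0,
    offset: float = _DEFAULT_OFFSET,
    screen: float = _DEFAULT_SCREEN,
) -> SolvationResult:
    """GB/SA solvation free energy per frame plus the weighted ensemble mean."""
    topo = ensemble.topology
    idx = topo.solute_indices()
    q = topo.partial_charges()[idx]
    if weights is None:
        weights = ensemble.effective_weights()
    g_pol = np.empty(ensemble.n_frames)
    g_np = np.empty(ensemble.n_frames)
    for k, fr in enumerate(ensemble.frames):
        radii = effective_born_radii(fr, topo, offset=offset, screen=screen)
        g_pol[k] = gb_polarization_energy(
            fr, q, radii, eps_in=eps_in, eps_out=solvent_model.dielectric,
            solute_indices=idx,
        )
        surf = shrake_rupley(fr, topo, probe_radius, n_sphere_points, PolarPolicy())
        g_np[k] = (
            solvent_model.surface_tension_gamma * surf.total_sasa
            + solvent_model.surface_offset_b
        )
    return SolvationResult(
        solvent=solvent_model.name,
        per_frame_g_polar=g_pol,
        per_frame_g_nonpolar=g_np,
        weights=np.asarray(weights, dtype=float),
    )


def delta_g_loss(
    aqueous_ensemble: ConformerEnsemble,
    chloroform_ensemble: ConformerEnsemble | None = None,
    water_model: SolventModel = WATER,
    chcl3_model: SolventModel = CHLOROFORM,
    weights_aqueous: np.ndarray | None = None,
    weights_chloroform: np.ndarray | None = None,
    **gb_kwargs,
) -> float:
    """Solvation free-energy loss (kcal/mol) on water→chloroform transfer.

    ΔG_loss = ⟨G_solv in chloroform over the chloroform ensemble⟩ −
    ⟨G_solv in water over the aqueous ensemble⟩. When no chloroform
    ensemble is given, both solvents are evaluated on the aqueous ensemble
    (single-ensemble mode; aqueous-derived descriptors are typically the
    better-behaved choice for permeability correlation).
    """
    if chloroform_ensemble is None:
        chloroform_ensemble = aqueous_ensemble
        if weights_chloroform is None:
            weights_chloroform = weights_aqueous
    else:
        if chloroform_ensemble.topology.n_atoms != aqueous_ensemble.topology.n_atoms:
            raise ValueError("aqueous and chloroform ensembles differ in topology")
    g_cl = solvation_free_energy(
        chloroform_ensemble, chcl3_model, weights=weights_chloroform, **gb_kwargs
    )
    g_aq = solvation_free_energy(
        aqueous_ensemble, water_model, weights=weights_aqueous, **gb_kwargs
    )
    return g_cl.g_solv_mean - g_aq.g_solv_mean
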