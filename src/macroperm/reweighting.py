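"""Boltzmann temperature reweighting of high-temperature ensembles.

High-temperature sampling explores conformational space efficiently but
distorts state populations. Given per-frame potential energies U_i sampled
at T_sim, the room-temperature (T_target) ensemble is reconstructed by
assigning each frame the weight

    w_i ∝ exp[-(β_target - β_sim) · U_i],    β = 1 / (k_B T)

with k_B = 0.0083145 kJ/(mol·K). This is exact for samples drawn from the
canonical distribution at T_sim in a fixed potential. The reliability of
the reweighted ensemble is tracked through the Kish effective sample size
ESS = 1 / Σ w_i²; a large temperature gap concentrates weight on few
low-energy frames and degrades ESS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ensemble_io import ConformerEnsemble

__all__ = ["KB_KJ_PER_MOL_K", "WeightVector", "boltzmann_reweight", "apply_weights"]

#: Boltzmann constant in kJ/(mol·K).
KB_KJ_PER_MOL_K = 0.0083145


@dataclass
class WeightVector:
    """Normalized per-frame weights for a T_sim -> T_target reweighting."""

    weights: np.ndarray
    t_sim: float
    t_target: float
    effective_sample_size: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")
        n = len(self.weights)
        if not (0 < self.effective_sample_size <= n + 1e-9):
            raise ValueError("effective sample size must lie in (0, n]")


def boltzmann_reweight(
    energies: np.ndarray,
    t_sim: float,
    t_target: float,
    ess_floor_fraction: float = 0.01,
) -> WeightVector:
    """Weights that map a T_sim canonical sample onto the T_target ensemble.

    Parameters
    ----------
    energies
        Per-frame potential energies, kJ/mol.
    t_sim, t_target
        Simulation and target temperatures, K (both > 0).
    ess_floor_fraction
        Warn when the effective sample size drops below this fraction of
        the frame count (default 1%).

    Notes
    -----
    The maximum exponent is subtracted before exponentiation, so the
    weights are invariant under a constant energy offset and numerically
    stable for large energy spreads. Equal temperatures or equal energies
    give uniform weights.
    """
    if t_sim <= 0 or t_target <= 0:
        raise ValueError("temperatures must be > 0")
    u = np.asarray(energies, dtype=float)
    if u.size == 0:
        raise ValueError("empty energy list")
    bad = ~np.isfinite(u)
    if bad.any():
        raise ValueError(f"non-finite energy at frame {int(np.flatnonzero(bad)[0])}")
    beta_sim = 1.0 / (KB_KJ_PER_MOL_K * t_sim)
    beta_target = 1.0 / (KB_KJ_PER_MOL_K * t_target)
    log_w = -(beta_target - beta_sim) * u
    log_w -= log_w.max()
    w = np.exp(log_w)
    w /= w.sum()
    ess = 1.0 / np.sum(w**2)
    if ess < ess_floor_fraction * u.size:
        warnings.warn(
            f"effective sample size {ess:.1f} below {ess_floor_fraction:.0%} of "
            f"{u.size} frames; reweighted averages may be unreliable",
            stacklevel=2,
        )
    return WeightVector(
        weights=w, t_sim=t_sim, t_target=t_target, effective_sample_size=ess
    )


def apply_weights(
    ensemble: ConformerEnsemble, weight_vector: WeightVector
) -> ConformerEnsemble:
    """Attach reweighting weights to an ensemble for downstream averaging."""
    if len(weight_vector.weights) != ensemble.n_frames:
        raise ValueError(
            f"weight vector length {len(weight_vector.weights)} != "
            f"{ensemble.n_frames} frames"
        )
    return ensemble.with_weights(weight_vector.weights)
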