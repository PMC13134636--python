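"""Desolvation-cost-efficiency permeability model and library-level fits.

Under the solubility-diffusion picture, passive permeability is
P_e = K_p·D/d; for compounds of similar size the diffusion coefficient D
and membrane thickness d are roughly constant, so log P_e tracks the
thermodynamic cost of moving the molecule from water into the
low-dielectric membrane interior.

The desolvation cost efficiency (DCE) normalizes the water→chloroform
transfer penalty by the polar surface that must be desolvated:

    DCE = ΔG_loss / 3D_PSA            [kcal/(mol·Å²)]

A lower DCE means each square ångström of polar surface costs less to
bury — the signature of internal hydrogen-bond shielding. Chameleonic
compounds additionally pay the conformational work of reaching the
closed state; the corrected descriptor folds ΔG_conf (kJ/mol, converted
by 4.184) into the numerator:

    DCE_corr = (ΔG_loss + ΔG_conf/4.184) / 3D_PSA

An alternative two-regressor form, log10 P_e ~ a·DCE + b·ΔG_conf + c, is
also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble_io import PermeabilityTable
from .solvation import KCAL_TO_KJ

__all__ = [
    "DescriptorSet",
    "CorrelationResult",
    "SolubilityDiffusionParams",
    "dce",
    "corrected_descriptor",
    "fit_permeability_model",
    "fit_corrected_regression",
    "permeability_solubility_diffusion",
]


@dataclass
class DescriptorSet:
    """Ensemble-averaged descriptors for one compound.

    Energies: G_solv/ΔG_loss in kcal/mol, ΔG_conf in kJ/mol (converted
    internally where combined); areas in Å².
    """

    compound_id: str
    sasa_mean: float
    psa_3d_mean: float
    g_solv_water: float
    g_solv_chcl3: float
    delta_g_loss: float
    delta_g_conf: float | None = None

    @property
    def dce(self) -> float:
        return dce(self.delta_g_loss, self.psa_3d_mean)

    @property
    def dce_corrected(self) -> float:
        if self.delta_g_conf is None:
            return self.dce
        return corrected_descriptor(
            self.delta_g_loss, self.delta_g_conf, self.psa_3d_mean
        )

    def as_row(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "sasa_mean": self.sasa_mean,
            "psa_3d_mean": self.psa_3d_mean,
            "g_solv_water": self.g_solv_water,
            "g_solv_chcl3": self.g_solv_chcl3,
            "delta_g_loss": self.delta_g_loss,
            "delta_g_conf": self.delta_g_conf,
            "dce": self.dce,
            "dce_corrected": self.dce_corrected,
        }


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    descriptor_name: str
    series_label: str = ""
    excluded_compounds: tuple[str, ...] = ()


@dataclass(frozen=True)
class SolubilityDiffusionParams:
    kp: float              # unitless membrane/water partition coefficient
    d_coefficient: float   # cm²/s
    thickness: float       # cm

    def __post_init__(self) -> None:
        if min(self.kp, self.d_coefficient, self.thickness) <= 0:
            raise ValueError("all solubility-diffusion parameters must be > 0")


def dce(delta_g_loss: float, psa_3d_mean: float) -> float:
    """Desolvation cost efficiency ΔG_loss / 3D_PSA, kcal/(mol·Å²)."""
    if psa_3d_mean <= 0:
        raise ValueError(
            "3D_PSA must be > 0: a compound with no polar surface has undefined DCE"
        )
    return delta_g_loss / psa_3d_mean


def corrected_descriptor(
    delta_g_loss: float, delta_g_conf: float, psa_3d_mean: float
) -> float:
    """(ΔG_loss + ΔG_conf/4.184) / 3D_PSA — conformational-work-corrected DCE.

    ``delta_g_loss`` in kcal/mol, ``delta_g_conf`` in kJ/mol.
    """
    if psa_3d_mean <= 0:
        raise ValueError("3D_PSA must be > 0")
    return (delta_g_loss + delta_g_conf / KCAL_TO_KJ) / psa_3d_mean


def fit_permeability_model(
    descriptors: pd.DataFrame,
    permeability_table: PermeabilityTable,
    descriptor_name: str = "dce",
    series_filter: str | None = None,
) -> CorrelationResult:
    """OLS fit of log10(P_e) on one descriptor across a compound library.

    ``descriptors`` is a DataFrame with a ``compound_id`` column plus
    descriptor columns; compounds missing either the descriptor or a
    permeability row are excluded and listed on the result. With
    ``series_filter``, only permeability rows with that series label
    enter the fit.
    """
    perm = permeability_table.data
    if series_filter is not None:
        perm = perm[perm["series_label"] == series_filter]
    if descriptor_name not in descriptors.columns:
        raise ValueError(f"descriptor {descriptor_name!r} not in table")
    merged = perm.merge(descriptors[["compound_id", descriptor_name]],
                        on="compound_id", how="left")
    excluded = tuple(
        sorted(
            set(descriptors["compound_id"]) - set(merged["compound_id"])
        ) + merged.loc[merged[descriptor_name].isna(), "compound_id"].tolist()
    )
    merged = merged.dropna(subset=[descriptor_name])
    if len(merged) < 3:
        raise ValueError(f"need >= 3 matched compounds, have {len(merged)}")
    x = merged[descriptor_name].to_numpy(dtype=float)
    y = np.log10(merged["pe"].to_numpy(dtype=float))
    if np.ptp(x) == 0:
        raise ValueError(f"descriptor {descriptor_name!r} has zero variance")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(merged),
        descriptor_name=descriptor_name,
        series_label=series_filter or "",
        excluded_compounds=excluded,
    )


def fit_corrected_regression(
    descriptors: pd.DataFrame,
    permeability_table: PermeabilityTable,
    series_filter: str | None = None,
) -> dict:
    """Two-regressor form: log10(P_e) ~ a·DCE + b·ΔG_conf + c.

    Returns coefficients and the multiple correlation coefficient R
    (Pearson r between fitted and observed log10 P_e).
    """
    perm = permeability_table.data
    if series_filter is not None:
        perm = perm[perm["series_label"] == series_filter]
    merged = perm.merge(
        descriptors[["compound_id", "dce", "delta_g_conf"]], on="compound_id"
    ).dropna(subset=["dce", "delta_g_conf"])
    if len(merged) < 4:
        raise ValueError("need >= 4 compounds for the two-regressor fit")
    x = merged[["dce", "delta_g_conf"]].to_numpy(dtype=float)
    y = np.log10(merged["pe"].to_numpy(dtype=float))
    design = np.column_stack([x, np.ones(len(y))])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    r = float(np.corrcoef(fitted, y)[0, 1]) if np.ptp(fitted) > 0 else 0.0
    return {
        "coef_dce": float(coef[0]),
        "coef_delta_g_conf": float(coef[1]),
        "intercept": float(coef[2]),
        "multiple_r": r,
        "n": int(len(merged)),
    }


def permeability_solubility_diffusion(params: SolubilityDiffusionParams) -> float:
    """P_e = K_p·D/d in cm/s."""
    return params.kp * params.d_coefficient / params.thickness
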