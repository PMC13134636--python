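"""End-to-end orchestration: per-compound reports and library-level fits.

``run_compound`` chains the stages in the canonical order — reweight the
high-temperature aqueous ensemble to the target temperature, compute
surface and solvation descriptors, hydrogen-bond frequencies and hub
connectivity, open/closed macrostate populations with ΔG_conf, and the
DCE metrics — and returns a JSON-serializable report. ``run_library``
repeats that over a compound table and fits log10(P_e) against each
configured descriptor.

Reports are deterministic: identical config + seed give byte-identical
JSON (keys sorted, no timestamps); a SHA-256 hash of the canonical
config is embedded so any two reports can be compared for provenance.
Energies appear in both kcal/mol and kJ/mol to avoid unit confusion
between the solvation convention (kcal) and ΔG_conf (kJ).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .ensemble_io import (
    ConformerEnsemble,
    read_energy_csv,
    read_multi_model_pdb,
    read_permeability_csv,
)
from .hbonds import HBondCriteria, hbond_frequencies, hub_summary
from .macrostates import classify_open_closed, cluster_ensemble
from .permeability import (
    corrected_descriptor,
    dce,
    fit_corrected_regression,
    fit_permeability_model,
)
from .reweighting import apply_weights, boltzmann_reweight
from .solvation import (
    CHLOROFORM,
    KCAL_TO_KJ,
    WATER,
    SolventModel,
    solvation_free_energy,
)
from .surface import PolarPolicy, ensemble_surface_descriptors

__all__ = ["config_hash", "load_config", "run_compound", "run_library"]

_FIT_DESCRIPTORS = (
    "g_solv_water",
    "sasa_mean",
    "psa_3d_mean",
    "delta_g_loss",
    "dce",
    "dce_corrected",
)


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical (sorted-key JSON) form of the config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def load_config(path: str) -> dict:
    """Read a run configuration from TOML."""
    import tomllib

    with open(path, "rb") as fh:
        config = tomllib.load(fh)
    base = Path(path).parent
    for entry in config.get("compounds", {}).values():
        for key in ("aqueous_pdb", "nonpolar_pdb", "aqueous_energies",
                    "nonpolar_energies", "topology_overrides"):
            if key in entry and not Path(entry[key]).is_absolute():
                entry[key] = str(base / entry[key])
    if "permeability_csv" in config and not Path(config["permeability_csv"]).is_absolute():
        config["permeability_csv"] = str(base / config["permeability_csv"])
    return config


def _solvent_from(config: dict, name: str, default: SolventModel) -> SolventModel:
    params = config.get("solvents", {}).get(name)
    if not params:
        return default
    return SolventModel(
        name=name,
        dielectric=params.get("dielectric", default.dielectric),
        surface_tension_gamma=params.get(
            "surface_tension_gamma", default.surface_tension_gamma
        ),
        surface_offset_b=params.get("surface_offset_b", default.surface_offset_b),
    )


def _load_overrides(entry: dict) -> dict | None:
    path = entry.get("topology_overrides")
    if path is None:
        return None
    with open(path) as fh:
        raw = json.load(fh)
    if "named_hbonds" in raw:
        raw["named_hbonds"] = {
            k: tuple(v) for k, v in raw["named_hbonds"].items()
        }
    if "bonds" in raw:
        raw["bonds"] = [tuple(b) for b in raw["bonds"]]
    for key in ("donor_indices", "acceptor_indices"):
        if key in raw:
            raw[key] = set(raw[key])
    return raw


def _load_ensemble(entry: dict, which: str, medium: str,
                   t_sim: float) -> ConformerEnsemble:
    path = entry.get(f"{which}_pdb")
    if path is None:
        raise ValueError(f"missing {which} ensemble path")
    ens = read_multi_model_pdb(
        path,
        topology_overrides=_load_overrides(entry),
        medium=medium,
        simulation_temperature=t_sim,
    )
    energy_path = entry.get(f"{which}_energies")
    if energy_path:
        energies = read_energy_csv(energy_path)
        if len(energies) != ens.n_frames:
            raise ValueError(f"{which}: energy table does not match frame count")
        for fr, e in zip(ens.frames, energies):
            fr.potential_energy = float(e)
    return ens


def _reweighted(ens: ConformerEnsemble, t_target: float) -> ConformerEnsemble:
    energies = ens.energies()
    if energies is None or ens.simulation_temperature == t_target:
        return ens
    wv = boltzmann_reweight(energies, ens.simulation_temperature, t_target)
    return apply_weights(ens, wv)


def run_compound(config: dict, compound_id: str) -> dict:
    """Full single-compound analysis; returns a JSON-serializable report."""
    entry = config["compounds"][compound_id]
    t_target = float(config.get("t_target", 300.0))
    t_sim = float(entry.get("t_sim", t_target))
    criteria = HBondCriteria(
        max_da_distance=config.get("hbond_criteria", {}).get("max_da_distance", 3.5),
        min_dha_angle=config.get("hbond_criteria", {}).get("min_dha_angle", 135.0),
    )
    polar_policy = PolarPolicy(
        include_s=config.get("polar_policy", {}).get("include_s", False),
        include_f=config.get("polar_policy", {}).get("include_f", False),
    )
    water = _solvent_from(config, "water", WATER)
    chcl3 = _solvent_from(config, "chloroform", CHLOROFORM)
    cls_cfg = config.get("classification", {})
    mode = cls_cfg.get("mode", "rmsd-to-closed-reference")

    def fail(stage: str, exc: Exception) -> Exception:
        err = RuntimeError(f"[{compound_id}/{stage}] {exc}")
        err.__cause__ = exc
        return err

    try:
        aq = _load_ensemble(entry, "aqueous", "water", t_sim)
        aq = _reweighted(aq, t_target)
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise fail("reweight", exc)

    try:
        surf = ensemble_surface_descriptors(aq, polar_policy=polar_policy)
    except Exception as exc:
        raise fail("descriptors", exc)

    try:
        nonpolar = _load_ensemble(entry, "nonpolar", "chloroform", t_sim)
        nonpolar = _reweighted(nonpolar, t_target)
    except Exception as exc:
        if mode == "rmsd-to-closed-reference":
            raise fail("macrostates", exc)
        nonpolar = None

    try:
        g_aq = solvation_free_energy(aq, water)
        g_cl_src = nonpolar if nonpolar is not None else aq
        g_cl = solvation_free_energy(g_cl_src, chcl3)
        d_g_loss = g_cl.g_solv_mean - g_aq.g_solv_mean
    except Exception as exc:
        raise fail("solvation", exc)

    try:
        freqs = hbond_frequencies(aq, criteria)
        hub = (
            hub_summary(freqs, aq.topology,
                        threshold=config.get("hub_threshold", 0.1))
            if aq.topology.bridge_residue_id is not None
            else None
        )
    except Exception as exc:
        raise fail("hbonds", exc)

    try:
        if mode == "rmsd-to-closed-reference":
            max_cluster = int(config.get("cluster_max_frames", 200))
            sub = nonpolar
            if nonpolar.n_frames > max_cluster:
                stride = int(np.ceil(nonpolar.n_frames / max_cluster))
                sub = ConformerEnsemble(
                    topology=nonpolar.topology,
                    frames=nonpolar.frames[::stride],
                    medium=nonpolar.medium,
                    simulation_temperature=nonpolar.simulation_temperature,
                )
            clusters = cluster_ensemble(
                sub, rmsd_cutoff=cls_cfg.get("cluster_rmsd_cutoff", 1.0)
            )
            reference = sub.frames[clusters.representatives[0]].coordinates
            split = classify_open_closed(
                aq,
                mode=mode,
                closed_reference=reference,
                cutoff=cls_cfg.get("cutoff", 1.5),
                temperature=t_target,
                regularize=bool(cls_cfg.get("regularize", False)),
            )
        else:
            split = classify_open_closed(
                aq,
                mode="imhb-count",
                min_imhb_count=int(cls_cfg.get("min_imhb_count", 3)),
                criteria=criteria,
                temperature=t_target,
                regularize=bool(cls_cfg.get("regularize", False)),
            )
    except Exception as exc:
        raise fail("macrostates", exc)

    try:
        psa = surf["psa_3d_mean"]
        dce_value = dce(d_g_loss, psa) if psa > 0 else None
        dg_conf = split.delta_g_conf
        dce_corr = (
            corrected_descriptor(d_g_loss, dg_conf, psa)
            if psa > 0 and dg_conf is not None
            else dce_value
        )
    except Exception as exc:
        raise fail("dce", exc)

    return {
        "compound_id": compound_id,
        "provenance": {
            "config_hash": config_hash(config),
            "package_version": __version__,
            "seed": config.get("seed"),
            "t_sim": t_sim,
            "t_target": t_target,
            "hbond_criteria": {
                "max_da_distance": criteria.max_da_distance,
                "min_dha_angle": criteria.min_dha_angle,
            },
            "polar_policy": polar_policy.label(),
        },
        "descriptors": {
            "sasa_mean_A2": surf["sasa_mean"],
            "psa_3d_mean_A2": surf["psa_3d_mean"],
            "g_solv_water_kcal_mol": g_aq.g_solv_mean,
            "g_solv_water_kj_mol": g_aq.g_solv_mean * KCAL_TO_KJ,
            "g_solv_chcl3_kcal_mol": g_cl.g_solv_mean,
            "g_solv_chcl3_kj_mol": g_cl.g_solv_mean * KCAL_TO_KJ,
            "delta_g_loss_kcal_mol": d_g_loss,
            "delta_g_loss_kj_mol": d_g_loss * KCAL_TO_KJ,
            "dce_kcal_mol_A2": dce_value,
            "dce_corrected_kcal_mol_A2": dce_corr,
        },
        "macrostates": {
            "p_open": split.p_open,
            "p_closed": split.p_closed,
            "p_other": split.p_other,
            "temperature_K": split.temperature,
            "delta_g_conf_kj_mol": split.delta_g_conf,
            "delta_g_conf_kcal_mol": (
                split.delta_g_conf / KCAL_TO_KJ
                if split.delta_g_conf is not None else None
            ),
            "classification_mode": split.classification_mode,
        },
        "hbonds": {
            "named_frequencies": dict(sorted(freqs.named_frequencies.items())),
            "total_intramolecular": freqs.total_intramolecular,
            "total_solute_solvent": freqs.total_solute_solvent,
            "hub": None if hub is None else {
                "residue_id": hub.residue_id,
                "partner_residues": sorted(hub.partner_residues),
                "degree": hub.degree,
                "donor_and_acceptor": hub.donor_and_acceptor,
                "threshold": hub.threshold,
            },
        },
    }


def run_library(config: dict, output_dir: str | None = None) -> dict:
    """Per-compound reports plus log10(P_e)-vs-descriptor fits.

    Writes ``<compound_id>.json`` per compound and ``library.json`` with
    the fit summary when ``output_dir`` is given.
    """
    import pandas as pd

    compounds = config.get("compounds", {})
    if len(compounds) < 3:
        raise ValueError("need >= 3 compounds with permeability rows")
    perm = read_permeability_csv(config["permeability_csv"])
    reports = {cid: run_compound(config, cid) for cid in sorted(compounds)}
    rows = []
    for cid, rep in reports.items():
        d = rep["descriptors"]
        rows.append(
            {
                "compound_id": cid,
                "g_solv_water": d["g_solv_water_kcal_mol"],
                "sasa_mean": d["sasa_mean_A2"],
                "psa_3d_mean": d["psa_3d_mean_A2"],
                "delta_g_loss": d["delta_g_loss_kcal_mol"],
                "dce": d["dce_kcal_mol_A2"],
                "dce_corrected": d["dce_corrected_kcal_mol_A2"],
                "delta_g_conf": rep["macrostates"]["delta_g_conf_kj_mol"],
            }
        )
    table = pd.DataFrame(rows)
    fits = {}
    series = [None] + sorted(
        s for s in perm.data["series_label"].unique() if s
    )
    for name in _FIT_DESCRIPTORS:
        for s in series:
            key = f"{name}|{s or 'all'}"
            try:
                res = fit_permeability_model(table, perm, name, series_filter=s)
            except ValueError as exc:
                fits[key] = {"error": str(exc)}
                continue
            fits[key] = {
                "slope": res.slope,
                "intercept": res.intercept,
                "pearson_r": res.pearson_r,
                "p_value": res.p_value,
                "n": res.n,
                "excluded_compounds": list(res.excluded_compounds),
            }
    try:
        fits["regression|dce+delta_g_conf"] = fit_corrected_regression(table, perm)
    except ValueError as exc:
        fits["regression|dce+delta_g_conf"] = {"error": str(exc)}
    summary = {
        "provenance": {
            "config_hash": config_hash(config),
            "package_version": __version__,
            "seed": config.get("seed"),
        },
        "fits": fits,
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cid, rep in reports.items():
            (out / f"{cid}.json").write_text(
                json.dumps(rep, indent=2, sort_keys=True) + "\n"
            )
        (out / "library.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        table.sort_values("compound_id").to_csv(
            out / "descriptors.csv", index=False
        )
    return {"summary": summary, "reports": reports, "descriptor_table": table}
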