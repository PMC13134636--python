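# macroperm

Conformational-ensemble analysis of passive membrane permeability for
chameleonic macrocycles and macrobicyclic peptidomimetics.

## The problem

Polar macrocyclic peptidomimetics can cross membranes passively despite
carrying substantial polar surface, provided they are *chameleonic*: in
water they populate "open" conformers with solvent-exposed polar groups,
while in a nonpolar medium they collapse into "closed" conformers whose
polar groups are shielded by intramolecular hydrogen bonds (IMHBs),
often organized around a single bridging residue that donates and
accepts hydrogen bonds to several partners at once (a hydrogen-bond
*hub*). This package quantifies that behavior from conformer ensembles
and turns it into a permeability model. It is aimed at computational
and medicinal chemists who already have conformer ensembles (e.g. from
enhanced-sampling MD) and want ensemble-level permeability descriptors
with a fully testable, deterministic implementation.

## The model

Under the solubility–diffusion picture, P_e = K_p·D/d; for congeneric
compounds log₁₀ P_e tracks the thermodynamic cost of moving the solute
from water into the low-dielectric membrane interior. The package
computes, per compound, over a (reweighted) conformer ensemble:

- **SASA** and **3D_PSA** — Shrake–Rupley solvent-accessible surface
  area and its polar-atom share (N, O, and H bonded to N/O by default),
  on a deterministic golden-spiral point set;
- **G_solv(water), G_solv(CHCl₃), ΔG_loss** — generalized-Born/
  surface-area solvation free energies in the two dielectrics and the
  transfer penalty ΔG_loss = ⟨G_solv(CHCl₃)⟩ − ⟨G_solv(water)⟩;
- **ΔG_conf = −RT·ln(P_closed/P_open)** — the conformational work of
  shifting the aqueous open/closed equilibrium to the membrane-
  permeating closed state (R = 8.314 J/(mol·K), T = 300 K), with the
  populations obtained by RMSD- or IMHB-based classification of the
  reweighted ensemble;
- **DCE = ΔG_loss / 3D_PSA** — the *desolvation cost efficiency*, the
  energy penalty paid per Å² of polar surface, and its corrected form
  **(ΔG_loss + ΔG_conf/4.184) / 3D_PSA**.

High-temperature ensembles are mapped to the target temperature by
Boltzmann reweighting, w_i ∝ exp[−(β_target − β_sim)·U_i], with the
Kish effective sample size reported. Library-level permeability fits
are ordinary least squares of log₁₀(P_e) on each descriptor, with
Pearson r and p-value.

A first-class synthetic-data module generates every input with known
ground truth (planted two-state thermodynamics, planted hydrogen-bond
hub networks, planted descriptor→permeability laws), so the whole chain
is testable without any MD engine.

## Worked example

A chameleonic compound with an 11.5 % closed population planted at
300 K, sampled as a 20,000-frame "high-temperature" ensemble at 500 K,
then reweighted and classified:

```python
import numpy as np
import macroperm as mp
from macroperm.synthetic import TwoStateSpec

topo, closed, open_ = mp.make_macrocycle_topology(seed=0)
spec = TwoStateSpec(topology=topo, template_closed=closed, template_open=open_,
                    n_frames=20_000, p_closed_target=0.115,
                    t_sim=500.0, t_target=300.0, seed=1)
ens = mp.make_two_state_ensemble(spec)

wv = mp.boltzmann_reweight(np.asarray(ens.energies()), t_sim=500.0, t_target=300.0)
ens = mp.apply_weights(ens, wv)
print(f"effective sample size: {wv.effective_sample_size:.0f} / {ens.n_frames}")

split = mp.classify_open_closed(ens, mode="rmsd-to-closed-reference",
                                closed_reference=closed.coordinates)
print(f"p_open = {split.p_open:.1%}, p_closed = {split.p_closed:.1%}")
print(f"delta_G_conf = {split.delta_g_conf:+.2f} kJ/mol")

table = mp.hbond_frequencies(ens)
hub = mp.hub_summary(table, topo)
print(f"bridge hub: degree {hub.degree}, donor+acceptor: {hub.donor_and_acceptor}")
print(f"Hb1 frequency: {table.named_frequencies['Hb1']:.3f}")
```

which prints:

```
effective sample size: 18640 / 20000
p_open = 88.3%, p_closed = 11.7%
delta_G_conf = +5.04 kJ/mol
bridge hub: degree 4, donor+acceptor: True
Hb1 frequency: 0.117
```

The recovered closed population (11.7 %) matches the planted 11.5 %
within sampling error; the positive ΔG_conf says the closed state is
the aqueous minority, i.e. the compound pays ≈5 kJ/mol of
conformational work on top of its desolvation penalty. The named bond
Hb1 (bridge → partner residue) is present in exactly the closed
fraction of frames, and the bridging residue hub donates to two
residues and accepts from two others.

A command-line interface mirrors the stages
(`macroperm simulate|reweight|descriptors|solvation|hbonds|macrostates|fit|run`);
`macroperm run --config run.toml --out reports/` executes the whole
per-compound and library analysis from one TOML file and writes
deterministic JSON reports.

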