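# Methods

This note documents the models implemented in `macroperm`, the defaults
and their rationale, the numerical choices, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Data model and IO

Ensembles are multi-model PDB (via biotite) or concatenated XYZ blocks;
coordinates are Å, energies kJ/mol, atom indices 0-based internally
(PDB serials are 1-based on disk only). PDB carries no chemistry beyond
elements and residues, so partial charges, van der Waals radii, bonds,
donor/acceptor flags, named hydrogen-bond labels and the bridge-residue
annotation travel in a JSON/dict *topology overrides* side channel
(`topology_overrides_dict` serializes a topology into it). Defaults when
no override is given: Bondi-style radii keyed by element, zero partial
charges, donors = N/O/S bearing ≥1 H (hydrogens attached by bond list,
or by a 1.3 Å nearest-heavy-atom rule when no bonds are known),
acceptors = N/O. Explicit solvent is tagged by residue name (HOH, WAT,
SOL, TIP3, CL3, CHL; configurable) and excluded from all solute-only
analyses. Permeability tables are CSV with P_e in 10⁻⁶ cm/s;
below-detection rows (P_e ≤ 0) are dropped with a warning rather than
imputed, since the permeability fits use measured values only.

## Temperature reweighting

Frames sampled canonically at T_sim are mapped to T_target with

w_i ∝ exp[−(β_target − β_sim)·U_i],  β = 1/(k_B T),  k_B = 0.0083145 kJ/(mol·K).

This is exact single-state Boltzmann reweighting of a fixed potential
— a deliberate simplification of published potential-energy-surface
reconstruction schemes, adopted because it has an analytic two-state
oracle the tests can verify against. The maximum exponent is subtracted
before exponentiation, making the weights invariant under constant
energy offsets and numerically stable. The Kish effective sample size
ESS = 1/Σw² is always reported; below 1 % of the frame count a warning
is emitted, because reweighting across large temperature gaps
concentrates all weight on a few low-energy frames. T_sim is a required
input and is never defaulted. No multi-temperature estimator
(WHAM/MBAR) is provided.

## Surface descriptors

Shrake–Rupley SASA uses a deterministic golden-spiral (Fibonacci
lattice) point set, 960 points per atom by default, probe radius 1.4 Å,
on spheres of radius vdW + probe. Determinism was preferred over random
point sampling so that descriptor values are exactly reproducible;
doubling the point count changes a random 20-atom cluster's SASA by
< 0.5 %. Two atoms at identical coordinates make the buried/exposed
split ill-defined and raise an error.

3D_PSA sums per-atom SASA over the polar set. The default polar set is
N, O, and hydrogens bonded to N/O, following classical polar-surface-
area conventions; sulfur and fluorine are excluded by default (a
fluorine-rich bridge would otherwise dominate the PSA) but both can be
enabled by policy, and the active policy is echoed in every report.

RMSD uses Kabsch superposition (proper rotations only) via scipy's
`Rotation.align_vectors`, with the residual recomputed explicitly after
applying the rotation because the reported `rssd` loses precision to
cancellation for near-congruent sets. "All-heavy-atom" selections are
every non-hydrogen solute atom.

## Implicit solvation and ΔG_loss

G_solv = G_polar + γ·SASA + b, with the polar term a Still-type
generalized-Born energy:

E = −½ · 332.06 · (1/ε_in − 1/ε_out) · Σ_ij q_i q_j / f_GB(r_ij, R_i, R_j),
f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))).

Effective Born radii come from Hawkins–Cramer–Truhlar pairwise
descreening (uniform screening factor 0.8, radius offset 0.09 Å) with
the Onufriev–Bashford–Case OBC-II tanh rescaling (α, β, γ = 1.0, 0.8,
4.85). An isolated atom's effective radius is exactly its intrinsic
radius minus the offset; burial only increases it. Defaults: ε_in = 1,
water ε = 78.5, chloroform ε = 4.81, γ = 0.00542 kcal/(mol·Å²),
b = 0.92 kcal/mol, with the same γ/b in both solvents so that
ΔG_loss = ⟨G_solv(CHCl₃)⟩ − ⟨G_solv(water)⟩ is driven entirely by the
polar desolvation physics the DCE metric targets (per-solvent overrides
are available). Energies are kcal/mol internally; the single conversion
constant 4.184 is applied wherever ΔG_conf (kJ/mol) is combined.

This GB/SA model is a transparent desk-scale implementation chosen for
its analytic oracles (the Born ion is reproduced to 10⁻⁶ relative
error); its *absolute* values are not comparable to force-field or
experimental solvation energies, and only relative/correlational
structure across a compound series should be interpreted. Whether
ΔG_loss should be evaluated on two medium-specific ensembles or on the
aqueous ensemble alone is genuinely open; both modes exist
(`delta_g_loss` with or without a chloroform ensemble), the
single-ensemble mode being the pragmatic default when only aqueous
sampling is trusted.

## Hydrogen bonds and the hub

A hydrogen bond is a (donor-heavy, H, acceptor) triple with
donor–acceptor distance ≤ 3.5 Å and D–H···A angle ≥ 135°, common
MD-analysis conventions; both are configurable and echoed in reports.
Donor and acceptor must be in different residues, or, within one
residue, separated by ≥ 3 covalent bonds — this excludes degenerate
contacts inside a single functional group. Same-residue pairs with no
bond path on record are excluded (separation unverifiable). Bond kinds
are "intramolecular" (both partners solute) or "solute-solvent";
solvent–solvent pairs are ignored. For solute-only ensembles no
solute–water bond can be counted; the polar SASA of the group is the
documented proxy for solvent exposure in that case.

Pair frequencies are weighted fractions of frames containing the pair
(at least one H of the donor bonding the acceptor), hence lie in [0,1]
and are monotone non-increasing under stricter criteria. Named bonds
are always reported, at frequency 0 when absent. The hub summary counts
partner residues connected to a chosen residue at frequency ≥ 0.1
(default) and flags whether it simultaneously donates and accepts.

## Macrostates and ΔG_conf

Clustering is the greedy quality-threshold (Daura-style) rule on
all-heavy-atom Kabsch RMSD, cutoff 1.0 Å by default: the unassigned
frame with the largest weighted neighbour count seeds the next cluster
(ties → lowest frame index), clusters are renumbered by descending
population, and each cluster's representative is its weighted medoid.
The procedure is deterministic given frame order.

Open/closed classification has two modes, because no single rule is
canonical: (1) *rmsd-to-closed-reference* — closed iff all-heavy-atom
RMSD to a closed reference ≤ 1.5 Å; the recommended reference is the
nonpolar-medium top-cluster medoid, mirroring the chameleonic picture
in which the closed state dominates in chloroform. With an additional
open reference, frames near neither are "other"; frames within cutoff
of both are assigned closed and logged. (2) *imhb-count* — closed iff
≥ k named IMHBs are present (default k = 3). Then

ΔG_conf = −R·T·ln(P_closed/P_open),  R = 8.314 J/(mol·K), T = 300 K,

positive when closed is the aqueous minority. Zero populations are an
error unless the Laplace pseudo-weight ε = 1/(n+2) regularization is
requested explicitly (and logged). Note the gas constant here (8.314)
and the reweighting Boltzmann constant (0.0083145 kJ/(mol·K)) differ in
the fourth digit; each subsystem uses its conventional printed value,
and the discrepancy is far below every tolerance in use.

## Permeability model

DCE = ΔG_loss/3D_PSA; corrected form (ΔG_loss + ΔG_conf/4.184)/3D_PSA.
The correction's functional form is not uniquely determined by the
physical argument (desolvation penalty plus conformational work), so
both the numerator-additive form and a two-regressor alternative
log₁₀P_e ~ a·DCE + b·ΔG_conf + c are computed and reported; neither is
claimed to be canonical. Fits are OLS of log₁₀(P_e) on one descriptor
(scipy `linregress`: slope, intercept, Pearson r, two-sided p), require
≥ 3 matched compounds and nonzero descriptor variance, and list every
excluded compound. Series filtering (e.g. restricting to one
bridge-residue series) is a row filter on the permeability table, never
hard-coded. A compound with zero polar surface has undefined DCE and is
reported as missing rather than given a sentinel value.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of spec + one integer seed (substreams
split with `numpy.random.SeedSequence`), so all outputs are bit-stable.

- *Toy macrobicycle*: ~33 atoms, 8 bead-cluster "residues". The closed
  template plants exactly four ideal hydrogen bonds (2.9 Å, collinear)
  between the bridge and four distinct partners — the bridge donates
  two and accepts two — while the open template displaces every
  non-bridge residue by 7 Å, breaking all of them. Open and closed
  templates differ by > 3 Å heavy-atom RMSD, so 0.05 Å coordinate
  jitter can never flip a classification.
- *Two-state ensembles*: the energy gap ΔE is chosen so the planted
  closed population holds at the target temperature
  (ΔE = −k_B·T·ln(p/(1−p))); frames are drawn Bernoulli at the
  simulation temperature with energies 0/ΔE plus N(0, 0.1 kJ/mol)
  noise — small against any planted gap ≥ 1 kJ/mol, so the analytic
  populations remain valid within stated tolerances.
- *Compound libraries*: descriptors uniform on a range, log₁₀P_e
  linear with Gaussian noise; the population Pearson r is analytic
  (r = s·σ_x/√(s²σ_x² + σ_noise²)), and `noise_sd_for_target_r` inverts
  it to plant a chosen correlation.

What passing tests on these data *show*: the estimators (reweighting,
classification, frequencies, fits) are correct against analytic ground
truth. What they do *not* show: force-field accuracy, sampling
convergence of real MD, realistic peptide geometry, explicit-solvent
effects, or that the GB/SA energies match experiment — none of which
the package claims.

## Problem sizes and determinism

Statistical recovery tests use 20,000-frame ensembles (binomial
standard errors ≈ 0.2–0.4 % on populations), 40–200-compound libraries,
and 200 fit replicates for confidence-interval coverage; the pipeline
orchestration tests use 30–150-frame ensembles per compound, which
keeps full-pipeline runs at interactive speed while leaving every
statistical tolerance comfortably testable. Nonpolar ensembles are
strided down to ≤ 200 frames before O(n²) clustering. Reports are JSON
with sorted keys and no timestamps; a SHA-256 of the canonical config
is embedded, and two runs at the same seed are byte-identical.

## Known limitations

- GB/SA absolute energies are not transferable to other codes'
  G_solv scales; use within-series comparisons only.
- No Poisson–Boltzmann, salt, or explicit-solvent free energies; no
  analytic (Gauss–Bonnet) surfaces; no π- or halogen-bond detection.
- Binary trajectory formats (DCD/XTC/TRR) are not read; convert to
  multi-model PDB or XYZ first.
- The open/closed rule is parameter-dependent (reference structure and
  RMSD cutoff, or named-bond list and k); published population figures
  from other workflows depend on their unstated parameters, and this
  package does not claim to reproduce any specific printed population.
- No Markov-state modelling or kinetics: ΔG_conf is purely a
  population thermodynamic quantity.
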