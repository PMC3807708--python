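# Methods

This note documents the models, conventions and numerical choices behind
`mutbind`, and what the synthetic benchmarks do and do not demonstrate.

## Interface definition and structural comparisons

A receptor residue belongs to the binding interface if the minimum distance
between any of its non-hydrogen atoms and any non-hydrogen ligand-chain atom
is **≤ cutoff** (default 6.0 Å). Choices baked into this definition:

* *Non-hydrogen atoms only.* Crystal structures at ~3 Å resolution carry no
  hydrogens, so including them would make the result depend on whether a
  deposition was protonated. Hydrogens are parsed and retained but flagged
  and ignored by the distance criterion.
* *Closed interval.* "Within 6 Å" is read inclusively; a residue at exactly
  the cutoff is in. The cutoff is configurable.
* *Waters and heterogroups excluded* by default (configurable), so ordered
  solvent cannot bridge an interface.
* *Model 1 only* for multi-model files; alternate conformations collapse to
  the highest-occupancy conformer, ties broken by altloc letter ascending.

Interfaces from crystallographically independent copies of the same receptor
chain are equivalenced by author residue number + insertion code (the copies
share one sequence) and unioned; an optional per-selection offset maps
deviant numbering onto the reference.

Superposition uses the standard SVD (Kabsch) least-squares fit
(`Bio.SVDSuperimposer`). By default the rotation is optimized **on the same
atom set the RMSD is evaluated on** (main-chain N, CA, C, O of the selected
residues) — the natural reading for interface-vs-control comparisons. A
`fit_on_same_atoms=False` mode fits on all residues common to both chains
and evaluates only the selection, as a sensitivity check. Distance search
uses a k-d tree; the test suite checks it against an exhaustive all-pairs
scan, and superposition against an independent optimal-rotation oracle
(`scipy.spatial.transform.Rotation.align_vectors`).

Per-residue RMSF is computed about the ensemble mean position, per atom,
then averaged over the residue's atoms.

## Conservation

Conservation of an alignment column is the fraction of sequences whose
aligned residue **equals the reference residue** (the receptor being
engineered), not the consensus: the veto exists to protect the residue that
would be mutated. The modal residue is reported alongside for display. Gaps
count as mismatches; columns where the reference is gapped are skipped; the
reference itself counts in numerator and denominator (the *n*-of-*n*
convention, configurable). Positions **strictly above** the threshold
(default 0.65) are vetoed. Structure numbering maps to reference (UniProt-
style) numbering by a constant offset (default 17 for the IFN-γ receptor
system, `structure = reference − 17`).

## ΔΔG bookkeeping and selection

Energies are kJ/mol throughout (a kcal/mol import flag converts by 4.184);
negative = favorable. Two energy types per mutation and interface:
*stability* (of the mutated complex) and *affinity* (of binding). The scan
itself is an external producer (empirical force field and/or MD snapshots);
this package consumes its TSV output.

Snapshot ensembles are combined by the arithmetic mean per
(mutation, interface, type) key, with the population SD reported alongside.

Selection (stabilize mode): affinity ΔΔG < 0 **and** stability ΔΔG < 0 on
**all** interfaces, and conservation ≤ threshold. The thresholds default to
a strict 0 kJ/mol — "favorable means negative" — and are configurable, since
any additional margin is a judgment call. Destabilize mode (control
variants): affinity ΔΔG > 0 on all interfaces while stability ΔΔG < 0
(weaken binding without unfolding the receptor); no conservation veto, since
controls are chosen for effect, not safety. Ranking is by best (most
negative) affinity ΔΔG ascending in stabilize mode, by least-positive
affinity in destabilize mode; ties break by position, then mutant residue
alphabetically — a documented convention, since none is canonical.

Multi-mutant design: every subset of 2..max_order singles whose pairs are
≥ 25 residues apart in sequence **and** > 20 Å apart between wild-type CA
atoms. CA–CA distance is the convention chosen for "apart in 3D space";
main-chain separation is what additivity arguments rest on. Three mutually
compatible singles yield 3 doubles + 1 triple (7 variants counting the
singles). Second-generation combinations chosen after experiments are
supplied explicitly, never auto-generated.

## Thermodynamics and statistics

* ΔΔG = −RT ln(K_d^WT / K_d^mut), R = 8.314 J/(mol·K), default
  T = 298.15 K (SPR affinities measured at 25 °C). Negative = tighter
  binder.
* K_d = k_d/k_a; fold change = K_d^WT / K_d^mut.
* Confidence half-width = t₍(1+level)/2, n−1₎ · esd/√n with esd the standard
  deviation of replicate K_d values. This reproduces published bounds of
  ±0.78 nM (esd 0.49 nM, n = 4) and ±2.6 nM (esd 2.1 nM, n = 5) exactly at
  the printed precision; a wild-type bound of ±0.85 nM back-computes to
  ±0.87 from the rounded esd 1.5 nM at n = 14 — attributable to esd
  rounding, and the formula is retained.
* Additivity: deviation = measured(multi) − Σ singles. Measurements carry an
  optional batch label; ΔΔG comparisons across batches are flagged in
  reports rather than suppressed.

## SPR: 1:1 Langmuir with drift

Association at analyte concentration C:
R(t) = R_eq (1 − e^(−(k_a C + k_d) t)), R_eq = k_a C R_max/(k_a C + k_d);
dissociation: R_end e^(−k_d (t − t_assoc)). Drift is a **single linear slope
per curve, continuous across phases** — the minimal reading of "Langmuir
with drift" (the vendor parameterization is proprietary, so this contract is
the module's definition). Mass-transport limitation is not modeled (high
flow rates justify the pseudo-first-order assumption).

Defaults mirror the experimental protocol: 90 s association, 10 min
dissociation, dt = 0.1 s, a 3-fold dilution series from 99 nM down to
1.2 nM. Double referencing: corrected = active − interspot −
(reference − reference's interspot), with linear resampling across grids.

Fitting: global nonlinear least squares (`scipy.optimize.least_squares`,
trf) with k_a, k_d, R_max shared across the concentration series
(log-parameterized to enforce positivity) and one drift slope per curve.
Initialization is data-derived — k_d from a log-linear regression of the
dissociation tail, k_a from the regression of observed rates on
concentration — with 5 multi-starts jittered log-uniformly within a decade
(fixed seed). Standard errors come from the Jacobian at the optimum
(delta method for the log-scale parameters). Noise-free self-consistency
recovers generator truth to < 10⁻⁶ relative; at 2% of R_max Gaussian noise,
the median error of k_a and k_d over 25 seeds is well under 5%.

## Thermal shift

Normalization: subtract the dye-only reference (linear resampling if
needed), then min-max scale to [0, 1]; a constant signal is a degenerate
curve (error). Tm is the maximum of the central-difference first derivative
on the measured grid (0.5 °C default), refined by a parabola through the
peak and its two neighbours. No smoothing by default; an optional odd-width
moving-average window on the derivative is available for noisy plates. A
derivative peak on the grid boundary is returned unrefined with a warning;
a curve whose derivative is never positive has no transition. Normalization
per curve (not per plate), since plate layouts vary.

## Synthetic data and what the benchmarks show

Every generator is a pure function of (seed, parameters), fans child seeds
out of a master seed by fixed documented offsets, and serializes its ground
truth next to the data.

* **Toy complex**: idealized straight backbone, 3.8 Å CA spacing, fixed
  main-chain offsets, no side chains. Planted interface residues sit exactly
  at the contact distance from a ligand atom; all other receptor atoms stay
  > 8 Å from every ligand atom, so any cutoff in (contact, 8 Å) must recover
  exactly the planted set.
* **MSA**: column match counts are `round(identity × n_seq)` clamped to
  [1, n], so realized conservation equals the planted rate up to that
  deterministic rounding (e.g. 0.66 over 32 sequences realizes 21/32).
* **ΔΔG matrix**: planted stabilizing mutations are negative on both types
  on all interfaces with margin ≥ 3·noise_sd; planted destabilizing ones
  positive-affinity/negative-stability. Background mutations are
  sign-unconstrained draws except that each is forced to fail on at least
  one interface, making "exactly the planted set is selected" well defined.
* **Sensorgrams**: the analytic model plus i.i.d. Gaussian noise, with
  drift-only reference and blank interspot channels.
* **Melt curves**: two-state sigmoid 1/(1+e^((Tm−T)/s)) with optional linear
  baselines and Gaussian noise — the standard thermal-shift shape.

These benchmarks validate the *computational* stages: geometry bookkeeping,
filtering logic, estimator correctness and noise robustness. They do not —
and cannot — validate force-field accuracy, real crystallographic disorder,
phylogenetic structure in alignments, mass-transport or rebinding artifacts
in SPR, or non-two-state unfolding; passing them says the pipeline computes
its definitions correctly, not that the design predictions are accurate for
any particular protein.

## Problem sizes used in the shipped checks

The reproduction script and test suite use 100 seeded toy complexes for the
interface oracle, 20 seeded matrices for selection recovery, 25 Monte-Carlo
seeds at 2% noise for the kinetic fit (dt = 1 s, 5 concentrations), dt =
0.5 s for the noise-free fit, and a 5-temperature panel for Tm recovery —
sizes at which every stochastic summary is stable to well within its
asserted tolerance across seeds.

## Known limitations

* No structure repair, loop modeling or protonation; inputs must parse.
* No alignment construction or phylogenetic weighting; the MSA is consumed
  as given, and heavily sampled clades therefore weigh more.
* No force-field energies: the ΔΔG matrices are inputs.
* SPR model is strictly 1:1 and drift-linear; heterogeneous-ligand,
  biphasic and mass-transport-limited data will fit poorly (by design,
  visible in the residuals).
* Tm is a derivative-peak estimate, not a thermodynamic (ΔH, ΔCp) fit.
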