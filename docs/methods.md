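# Methods

This note documents the models implemented, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and
the numerical choices that affect results.

## Binding model and CSP analysis

The titration analysis assumes fast exchange on the chemical-shift
timescale and 1:1 stoichiometry. The bound fraction of the protein at
total concentrations [P]t, [L]t (µM) is the physical root of the
binding quadratic,

    f_bound = ( s − √(s² − 4·[P]t·[L]t) ) / (2·[P]t),   s = [P]t + [L]t + Kd,

evaluated in the conjugate form 2·[L]t/(s + √(s² − 4[P]t[L]t)) to avoid
catastrophic cancellation when Kd ≫ [P]t, [L]t. The observed CSP is
CSP_max · f_bound per residue, with the weighted shift distance using
the conventional 1/5 ¹⁵N scaling.

**Peak tracking.** Assignments exist only for the free spectrum.
Residues are followed through the titration by chained
nearest-neighbour matching between consecutive points in the weighted
shift distance, gated at 0.15 ppm per step (configurable). Chaining
matters: total displacements of strongly perturbed residues routinely
exceed the gate while per-step displacements do not. A residue with no
candidate inside the gate at some point is flagged exchange-broadened
and stays flagged; two residues claiming the same candidate raises an
error rather than guessing. Ties are broken toward the
lower-numbered candidate with a logged warning.

**Interface call.** Threshold = mean + 2·SD of the CSPs of
non-broadened residues; population SD (ddof 0) and a strict `>` are the
defaults, both configurable. Broadened residues are reported as
qualitative interface evidence but never assigned a numeric CSP — any
sentinel magnitude would contaminate downstream statistics.

**Kd fitting.** The default is a global fit: one shared Kd, one
CSP_max ≥ 0 per residue, over residues whose endpoint CSP exceeds half
the interface threshold (binding-insensitive peaks contribute only
noise). Given Kd, each CSP_max is a linear least-squares amplitude, so
CSP_max is profiled out and the fit reduces to a one-dimensional
bounded minimisation over log Kd (bounds 10⁻³–10⁶ µM, xatol 10⁻¹²).
This is exact, deterministic, free of multi-start issues, and fast
enough that bootstrap resampling is cheap. A per-residue mode fits each
residue independently for heterogeneity checks.

**Uncertainties.** Nonparametric bootstrap: the bound titration points
are resampled with replacement (500 resamples by default, seeded) and
the fit repeated. The Kd standard error is the bootstrap SD. The 95%
interval is the *basic* bootstrap interval computed on the log-Kd
scale: Kd is positive with a right-skewed sampling distribution, and in
a calibration study at the package's default simulation conditions
(0.005 ppm peak noise, five bound points) the raw percentile interval
covered the generating Kd only ~85–87% of the time — a known
small-sample defect of the percentile method — while the basic
interval on the log scale covered ~98%. Parameter covariance is not
used for Kd: with five or six titration points the quadratic model's
curvature estimate is unreliable.

## Relaxation analysis

T1/T2 are fit per residue as I(t) = I0·e^(−t/T) by nonlinear least
squares in intensity space (log-space fitting fails on near-zero and
negative noisy points). Delay grids default to the standard eight-point
sets 0.002–0.4 s (T1) and 0.002–0.2 s (T2). Initialisation is
deterministic: I0 from the first intensity, T from the delay whose
intensity is closest to I0/e. Standard errors come from the fit's
parameter covariance. Data that do not decay — fitted T ≤ 0, a
non-finite covariance, or T beyond 100× the largest delay (the model
degenerating to a flat line) — raise a per-residue error that
`fit_series` logs and skips, so one bad peak does not kill a run.

hetNOE = I_sat/I_unsat with first-order error propagation. Flexibility
labels: hetNOE ≤ 0 "highly_flexible", < 0.5 "flexible" (a conventional
cutoff), otherwise "rigid".

## Ensemble statistics

Superposition is weighted Kabsch (proper rotations only; reflections
excluded; < 3 points or collinear sets are rejected). Ensemble
precision follows the RMSD-to-mean convention: all models are
iteratively superposed onto the evolving mean coordinates until the
mean moves < 10⁻⁶ Å, then mean (±SD, ddof 1)(min..max) of the
per-model RMSDs is reported over the stated residue range and atom
class. "Backbone" means N, Cα, C′ (oxygen excluded, configurable);
"heavy" is every non-hydrogen atom (hydrogens and alternate locations
are dropped at parse time). Per-residue RMSF uses the same superposed
frame.

Cross-structure comparison (`align_superpose`) pairs Cα atoms via
global sequence alignment, superposes, then iteratively removes pairs
deviating more than (current RMSD + 2.0 Å) and refits until the pair
set is stable — so a displaced loop does not inflate a core RMSD; the
final RMSD and pair count are both reported.

Restraint classes partition by sequence separation: short |i−j| ≤ 1,
medium 1 < |i−j| < 5, long |i−j| ≥ 5; the three counts always sum to
the total.

## Sequence and motif analysis

Global alignment is Needleman–Wunsch with BLOSUM62, gap open 10 /
extend 0.5 (Biopython's PairwiseAligner; first co-optimal traversal,
which is deterministic and prefers matches over gaps). Percent identity
defaults to identical columns over the *full alignment length including
gap columns*; an identities-over-shorter-sequence convention is
available because reported identities depend on this choice.

The ψKXE consensus scanner reports every window with ψ ∈ {L, I, V}
(extended set {L,I,V,M,F} by flag), the acceptor lysine second;
overlapping windows are all reported. The SIM scanner is a fixed,
versioned heuristic (`core4-hyd3-flank4-des2/v1`): a 4-residue core
with ≥ 3 residues from {V,I,L} whose two 4-residue flanks together
contain ≥ 2 residues from {D,E,S}; overlapping qualifying cores merge
into one hit. The SIM definition in the literature is prose, not a
formula; these thresholds reproduce the canonical PML-type and IE2-type
SIM peptides as single hits while rejecting poly-hydrophobic stretches
without acidic context. They are defaults, not truth.

## Synthetic data: what it emulates, what it does not

The generators invert the fitted models, which is exactly what makes
round-trip tests meaningful and also bounds what they prove.

* **Titrations** place free peaks uniformly in the amide region
  (¹H 7.0–10.0, ¹⁵N 103–133 ppm), rejection-sampled to a minimum
  weighted separation of 0.5 ppm — assigned peak lists come from
  resolved spectra, and the tracker assumes resolvable peaks.
  Default conditions: [P]t = 50 µM, ratios 0, 0.25, 0.5, 1, 2, 5 (the
  emulated protocol fixes only the 1:5 endpoint; the intermediate steps
  are a package choice), true Kd 31 µM, independent Gaussian noise per
  axis (0.005 ppm in the noisy studies), eight interface residues with
  ΔδH_max 0.05–0.25 and ΔδN_max 0.2–1.2 ppm. Exchange broadening is
  modelled as peak deletion above a per-residue bound-fraction cutoff;
  real intermediate-exchange lineshapes, peak overlap, and titration
  dilution effects are *not* modelled, so passing tests do not certify
  behaviour on crowded or slow-exchange spectra.
* **Relaxation** decays are ideal mono-exponentials with additive
  Gaussian noise; no cross-correlated relaxation or offset effects.
* **Ensembles** are smoothed self-avoiding Cα random walks (3.8 Å
  steps) carrying N, Cα, C′, O only, with isotropic per-atom noise —
  small in the core, large in designated flexible ranges. This is
  sufficient for superposition/RMSD/RMSF arithmetic, not a physical
  protein model: no side chains, no secondary structure, no covalent
  geometry beyond the Cα spacing.
* **Motif sequences** use uniform background over the 20 amino acids,
  so accidental hits near plants are possible; ground truth is a rescan
  of the final sequence, never the plant list alone.

## Problem sizes

Defaults keep every study small enough to re-run casually: 100
seeded replicates × 500 bootstrap resamples for the interval-coverage
study (the fit's variable-projection form makes each refit ~0.2 ms),
200 replicates for decay-fit bias, 50 seeds for ensemble Monte-Carlo
properties, 10×10×10 log grids for isotherm accuracy. The acceptance
script uses 50 coverage replicates.

## Known limitations

* One binding model (1:1, fast exchange); no cooperative, 2:1 or
  lineshape analysis.
* No model-free (Lipari–Szabo) interpretation of relaxation data.
* The SIM heuristic is deliberately simple; it does not score binding
  strength or orientation and will miss phospho-dependent SIMs.
* PDB reading reconciles mismatched model inventories by intersection;
  structures whose models genuinely differ in composition should be
  curated upstream.
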