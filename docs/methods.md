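# Methods

## The problem

Extracellular vesicles (EVs) dosed intravenously into rats are cleared
from plasma within hours, with kinetics that depend on the cell line that
produced the vesicles. The vesicles are tracked by a non-homologous tracer
miRNA packaged into them during production; plasma samples are quantified
by droplet digital PCR (ddPCR), normalized across analytical batches, and
the resulting concentration-time profiles are analyzed with a population
(nonlinear mixed-effects) compartmental model. `evkinetics` implements
that entire analysis chain, plus a synthetic-study generator so the chain
can be exercised and validated end to end without animal data.

## Quantification layer

**Droplet Poisson estimator.** A ddPCR reaction is partitioned into
~20,000 droplets of nominal volume 0.85 nL; a droplet is positive if it
received at least one template molecule. With copies Poisson-distributed
over droplets, the mean copies per droplet is `lambda = -ln(1 - p)` for
positive fraction `p`, and copies per reaction scale by the
reaction-to-droplet volume ratio. A fully positive well is saturated and
carries no copy-number information; it raises rather than returning a
guess.

**Standard curve and batch normalization.** Serial dilutions of a high
standard (~25,000 copies per 20 uL reaction at concentration factor 1;
factors ~0.001-5) define a reference line by ordinary least squares.
Every analytical batch carries its own high and low standards (low = 1/30
dilution of high); the batch's samples are mapped onto the reference scale
by the affine transform sending (batch low, batch high) to (reference low,
reference high). The affine form corrects both multiplicative efficiency
differences and additive background; a one-point scale-only mode is
available. The map makes the chain scale-equivariant: multiplying every
raw copy number in a batch by a constant leaves normalized output
unchanged.

**Conversion to EV-protein concentration.** Normalized copies are divided
by the batch's own dose-aliquot assay (copies per microgram of EV protein)
and the assayed plasma volume, and multiplied by the dilution factors:
`conc [ug/mL] = copies * dilution / (copies_per_ug * plasma_volume)`.
Anchoring each animal to its own dose aliquot absorbs differences in
tracer loading between cell lines and EV preparations. The exact
arithmetic of this conversion is a reconstruction — the upstream
description names the steps but not the formula — and is documented here
as such.

**QC.** Negative controls above 200 copies flag the batch; a flagged
sample set is reanalyzed (modeled as an independent re-extraction) and
excluded only on persistent failure. A separate screen flags cross-sample
contamination: after an IV bolus the concentration cannot rise late in the
time course, so a rise between consecutive samples (first of the pair at
>= 240 min) exceeding 5% of the animal's peak concentration excludes the
animal. The 5% threshold sits far above quantification noise near the
assay floor (<1% of peak in simulation) and far below any genuine
contamination event worth worrying about.

## Kinetic model

Mammillary compartment models with 1-3 compartments, parameterized by
volumes (mL) and clearances (mL/hr): elimination clearance(s) `cl`
(repeatable per site, so parallel-elimination ladder variants are
expressible), distributional clearances `cl2`, `cl3`, with optional
separate return clearances for the "unequal distribution rate" variants.
Micro-constants: `k10 = cl/v1`, `k12 = cl2/v1`, `k21 = cl2/v2`, etc.
Times are accepted in minutes everywhere (the sampling schedule is
2-1440 min) and converted to hours internally.

The IV-bolus solution is the eigendecomposition of the rate matrix — one
code path for every structural variant — with a dense matrix-exponential
fallback when the eigenvalue gap falls below 1e-10 (relative). The
batched version stacks all subjects (and all finite-difference
perturbations of the random effects) into one `numpy.linalg.eig` call;
this is what makes repeated fitting affordable.

Secondary parameters follow the conventional summaries:
elimination t1/2 = ln2 * (V1+V2+V3)/Cl (hr), compartment-2 distribution
t1/2 = ln2 * V2/Cl2 (hr), compartment-3 distribution t1/2 = ln2 * V3/Cl3
(reported in minutes), AUC = dose/Cl.

## Population model and FOCE-ELS estimation

Individual parameters are log-normal around typical values with optional
exponential covariate shifts: `P_i = theta * e^(covariate coef) * e^eta`,
`eta ~ N(0, Omega)` (diagonal by default; off-diagonal estimation via
log-Cholesky is a config option). Residual error is proportional
(`Cobs = C(1 + eps)`) or log-additive (`Cobs = C e^eps`, which cannot
simulate negative concentrations); both use SD `sigma`.

The marginal likelihood is approximated by first-order conditional
estimation: for each subject the conditional mode `eta-hat` is found by a
vectorized Newton search (Gauss-Newton curvature, backtracking line
search, all subjects in lockstep), and the subject's -2 log-likelihood is
evaluated from the linearization of the model about `eta-hat`. For
proportional error the residual variance is evaluated at the individual
prediction (FOCE "with interaction"). The log-additive model is evaluated
on the log scale with the Jacobian term (`2 * sum(log y)`) included, so
objective values — and therefore AIC — are comparable across the two
error models *within this implementation*. Absolute agreement with other
estimators' printed objective values is not a goal; AIC *differences*
between structures are the meaningful quantity.

Validation: on a small rig the objective agrees with numerical integration
of the exact marginal likelihood to ~0.02 (log-additive) and ~0.2
(proportional — the expected FOCE-I approximation error); both are well
inside the 0.5 tolerance the acceptance suite enforces.

**Optimization.** The outer problem runs L-BFGS-B on log(theta), raw
covariate coefficients, log-Cholesky omega and log(sigma) (positivity by
construction; box bounds at +/-40 on the log scale). Gradients are
forward differences with the perturbed inner problems warm-started from
the base point's conditional modes and capped at two Newton steps — the
perturbation of `eta-hat` is second order in the step, so the error is
far below the gradient tolerance. Because the warm-started inner modes
make the objective mildly history-dependent, L-BFGS-B can stall early;
the fitter therefore restarts from the incumbent with cold modes until
the gain drops below `restart_tol` (default 0.02 units, up to 10
restarts). Objective values above 1e5 are log-compressed (monotone) so
line searches remain numerically sane at absurd trial points. Exactly
zero observations under the log-additive model are floored at the
smallest positive observation / 100 (no lower limit of quantification is
enforced anywhere else).

**Initial estimates.** Noncompartmental heuristics stand in for manually
drawn best-fit lines: V1 from back-extrapolated C(0), Cl from
trapezoid-plus-tail AUC (terminal slope floored at a half-life of twice
the study span, since noisy late samples otherwise explode the tail), the
terminal volume split across peripheral compartments, distributional
clearances as fixed fractions of Cl.

**Uncertainty.** Standard errors come from the central-difference Hessian
of -2LL at the optimum (step 0.01 on the transformed scale); 95% CIs are
computed on the log scale and exponentiated, so bounds are positive and
asymmetric. A singular or indefinite Hessian yields `se = None`, never a
fabricated number. CWRES standardizes each subject's residual vector by
the Cholesky factor of the FOCE-linearized marginal covariance at
`eta-hat` (log scale under log-additive error).

## Model evaluation

**pcVPC.** Simulates replicate studies (default 1000) from the fitted
model at the original design using the log-additive residual model,
prediction-corrects observed and simulated values by
`pcY = Y * median(PRED in bin)/PRED` (bin-median form; the source method
names pcVPC without a formula), with 1-D k-means time bins (default 10,
initialized at unique-time quantiles, deterministic given seed), stratified
by cell line. Reported per stratum/bin: observed 5/50/95% quantiles and
the median plus 90% interval of each simulated quantile.

**Bootstrap.** Case resampling of animals with replacement, stratified
within cell-line arm to the original arm sizes (required so the cell-line
covariate stays estimable in every replicate); each replicate refits from
the base estimates with a bounded budget (200 outer iterations, one
restart). Failed or non-converged replicates are excluded and counted —
mirroring the real phenomenon of replicates driving a clearance to its
boundary. Summaries are the replicate mean and 2.5/97.5 percentiles.

## Group statistics

Per-animal secondary parameters come from the empirical-Bayes individual
parameters (`AUC_i = dose_i/Cl_i`). Between-cell-line comparison uses
Kruskal-Wallis (Wilcoxon rank-sum when k = 2) as omnibus at alpha = 0.05,
gating Steel-Dwass all-pairs comparisons (standardized pairwise rank
statistic referred to the studentized range, the nonparametric Tukey
analogue). For very small groups (<= ~6 per group) both tests offer exact
enumeration modes; at those sizes the chi-square and studentized-range
approximations are off by up to ~0.08 and ~0.18 in p respectively, so the
exact modes are the appropriate reference there, while the asymptotic
forms are the default at the study's n ≈ 10 per arm. Every reported
p-value is labeled with the test that produced it.

## Synthetic-data generator

The generator defines the study conditions:

- Three arms (clone 9 liver, RFL-6 lung fibroblast, RMC kidney mesangial),
  10 animals each, IV bolus, sampling at 2, 7.5, 15, 30, 60, 120, 240,
  480, 960, 1440 min.
- Arm kinetics: the fitted population estimates per cell line (V1 = 28 mL
  and Cl2 = 111 mL/hr shared; V2/V3/Cl/Cl3 arm-specific), i.e. the
  cell-line differences live on V2, V3, Cl and Cl3 as the covariate
  analysis found.
- Dose: 2,000 ug EV protein. The administered dose implied by the printed
  exposures (AUC x Cl ~ 2,000 ug for clone 9) differs from the stated
  preparation (1,000 ug at 2 ug/uL); the default follows the exposures and
  is configurable, not asserted as the source's value.
- Inter-animal variability: diagonal, ~40% CV (variance ln(1.16) = 0.148)
  on V1, V2 and Cl. The source states IIV was estimated for "various"
  parameters without listing them; three well-identified parameters keep
  the simulated studies estimable at n = 10/arm.
- Residual error: SD 0.45, applied log-additively by default (guarantees
  positive concentrations); proportional available. Recovery pipelines fit
  with the matching (log-additive) residual model.
- Assay layer: per-animal batches, each with high/low standards
  (25,000 / 833 copies nominal), a log-normal batch scale factor
  (SD 0.15 on the log scale) hitting samples, standards and dose aliquot
  alike, binomial droplet partitioning at 20,000 droplets/well, and
  log-normal negative-control background (median 60 copies, CV 110%,
  spanning roughly 20-266). Under this background ~9% of first-pass
  negative controls exceed 200 copies; with reanalysis modeled as an
  independent re-extraction, ~1% of batches fail persistently, so about a
  third of simulated 30-animal studies exclude one extra animal beyond any
  injected pathologies — as a real study might.
- Pathology injection: `contamination` spikes one animal's last sample
  well (tripping the late-rise screen); `qc_failure` forces one animal's
  negative control (and its reanalysis) above threshold.

What the generator does **not** emulate: assay drift within a batch,
false-positive background inside sample wells, catheter/handling losses,
time-varying clearance, inter-occasion variability, and any tissue-level
disposition. Passing recovery tests therefore demonstrate estimator
correctness under the stated model, not robustness to these real-world
violations.

## Problem sizes used in tests and the acceptance script

Simulation studies run at 20 replicates of the full 30-animal design;
the bootstrap uses 100 replicates (scaled down from the 1,000 of a full
analysis) on a single 10-animal arm — the arm size of the emulated study;
the pcVPC calibration uses 200 simulations (down from 1,000);
covariate-scan recovery uses 20 replicates of a 5+5 two-arm design with
the V2 effect at its realistic size (ln(752/3057) ~ -1.4). Decision tasks
(AIC ranking, covariate selection, bootstrap replicates) use a lighter
polish schedule than estimation tasks, since their AIC margins are orders
of magnitude above the final polish gain. These sizes were chosen to
estimate each rate or median with adequate precision while keeping a
complete run on a single CPU practical.

## Known limitations

- FOCE is an approximation; omega and sigma show the usual small-sample
  bias (they are only required to be recovered within 50% at this design).
- Cl is weakly identified in individual small studies: the terminal phase
  is barely sampled, so single-study estimates (and bootstrap replicates)
  occasionally collapse toward zero clearance with a compensating deep
  volume. Medians across studies are unbiased.
- The identity-resample bootstrap reproduces base estimates to optimizer
  termination tolerance (~1e-3 relative), not bit-exactly.
- Printed AIC values from other software are not reproducible (different
  likelihood constants); only AIC orderings are comparable.
- No infusion or absorption models; no Michaelis-Menten elimination.
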