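# Methods

This note documents the models, the synthetic world, the numerical choices
and the limitations of `lipidauth`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis pipeline

The authentication contrast throughout is binary: Yanchi lamb (region NX)
against pooled non-Yanchi lamb (GS and IM together). The two muscle parts —
*M. longissimus thoracis et lumborum* (LT) and knuckle meat (KM) — are
screened independently and their candidate sets intersected, so a marker
must generalize across muscle before it enters any classifier.

### QC filter (`preprocess`)

A lipid is kept iff its detection rate over pooled-QC injections is ≥ 0.5
and the coefficient of variation (population sd / mean of detected QC
values) is ≤ 0.3. Detection means a finite, strictly positive peak area.
Two open points resolved here: the CV is computed over QC injections only
(that is what pooled QC replicates are for), and the detection rate is also
computed over QC samples by default (configurable), since the source
protocol ties both thresholds to the QC injections. Missing values
surviving the filter are imputed as half the per-lipid minimum — the
conventional "below detection limit" surrogate in metabolomics.
Autoscaling (mean 0, unit population variance per lipid) is the default
before any projection model, matching the common default of metabolomics
platforms; Pareto scaling is available.

### Latent-variable models (`latent`)

PCA is an SVD of the centred matrix. PLS-DA is NIPALS PLS2 on a centred
one-hot class response; convergence tolerance 1e-12, at most 500
iterations, deterministic start from the largest-variance response column.
OPLS-DA (binary only) removes `n_orthogonal` class-orthogonal components
(default 1 — the standard chemometrics choice for a binary contrast)
before extracting the single predictive component; the orthogonal scores
are exactly uncorrelated with the class by construction. Sign convention
everywhere: the largest-|weight| coordinate of a component is positive.

VIP uses predictive components only (the usual OPLS-DA convention):
VIP_j = √(p · Σ_a SSY_a ŵ_aj² / Σ_a SSY_a) with unit-norm weights, so the
mean squared VIP is identically 1 and the 1.6 threshold measures "well
above average importance".

### Screening (`screening`)

Thresholds: p < 0.05 (Welch's unequal-variance t-test — the published
group SEs differ severalfold, making the pooled-variance test
inappropriate), FC > 4 or FC < 0.25, VIP > 1.6. Fold change is computed on
raw peak areas and oriented mean(non-NX)/mean(NX); this is the orientation
under which the carnitine markers, *higher* in Yanchi lamb, are reported
as down-regulated, and it is recorded in the report metadata. No multiple
testing correction is applied, mirroring the stated raw-p criteria;
Benjamini–Hochberg can be layered on by the caller. A candidate must pass
both the volcano rule and the VIP rule (Venn intersection); the cross-part
panel intersects the two per-part candidate sets and drops any lipid whose
direction disagrees between parts.

### Fisher stepwise discriminant (`discriminant`)

Classification functions follow the SPSS convention (coefficients
S_w⁻¹ μ_k, constant −½ μ_k′S_w⁻¹μ_k + log π_k, pooled covariance with the
n − g denominator). Priors are equal by default even though the design is
12 NX vs 24 non-NX: the near-symmetric constants of the published
functions indicate the "all groups equal" prior was used there, and for an
authentication task equal priors are the defensible default; they are
configurable. Backward elimination removes the feature with the smallest
partial F-to-remove — computed from the Wilks' lambda ratio,
F = (n−g−p+1)/(g−1) · (Λ_without/Λ_with − 1) — while that F is below 2.71
(the SPSS default, ≈ α 0.10; configurable, ∞ traces the panel down to one
feature). Among the traced models the final choice is the smallest whose
leave-one-out accuracy is within `cv_tolerance` (default 0) of the best:
fewer factors at no loss of discriminative accuracy. A singular pooled
covariance is ridge-regularized with 1e-8·trace(S_w)/p and a warning. Ties
in classification scores break to the first class and are logged.

Note that at α ≈ 0.10 a null feature survives elimination roughly 10 % of
the time; exact collapse to the informative subset is therefore typical
but not guaranteed, which the test suite pins with a fixed draw.

The published four-carnitine functions are shipped verbatim as
`REFERENCE_MODEL` — a fixed worked example for `classify` only. Refitting
them would require the original 36-sample dataset, which was never
deposited; the package makes no attempt to reproduce their coefficient
values from synthetic data.

### Networks (`swarmnet`)

Architecture 11-6-2: tanh hidden layer, softmax output, cross-entropy
loss; S = 11·6 + 6 + 6·2 + 2 = 86 parameters in a flat vector with a fixed
flattening order. (The source text's verbal definition of S sums node
counts and double-counts the hidden layer; the full weight-plus-bias count
is the only reading consistent with "number of optimisation parameters".)
Plain BP is full-batch gradient descent, learning rate 0.01, at most 1000
epochs, early stop when the loss improves < 1e-6 over 50 epochs, initial
weights drawn uniformly from the same ±2 box the optimizers search — that
box is wide for tanh units, which is precisely why a plain random start
can land in a saturated, slow-training region and why searching the start
helps. GA-BP and PSO-BP optimize the *initial* theta (the reading of
"optimized its parameters" consistent with the GA-BP/PSO-BP literature):
candidate fitness is the training cross-entropy after a 50-epoch BP
burn-in, and full BP training starts from the best candidate. PSO:
inertia 0.8, c1 = c2 = 1.5, velocities clamped to [−1, 1], positions to
[−2, 2], population 5, 30 updates. GA: tournament size 2, whole-arithmetic
crossover at rate 0.8, Gaussian per-gene mutation at rate 0.05 with sd
0.1·(box width), elitism 1, population 5, 30 generations. The search
budgets are kept at the published, statistically tiny values by default;
tests use larger populations where a convergence claim needs them. All
three trainers are deterministic under a seed.

### Evaluation (`evaluate`)

Stratified random 4:1 split with |train| = floor(0.8·n) — the rounding
that yields the published 28/8 for n = 36 and 4/1 for n = 5. (A
"round-half" rule would give 29/7 at n = 36.) Stratification by the NX
label is the default because an 8-sample test set drawn unstratified has a
non-trivial chance of losing a class; unstratified splitting is a flag.
Positive class for all metrics is NX. Ratios with zero denominators are
reported as 0 and flagged rather than NaN-propagated.

## The synthetic world (`synthetic_data`)

The generator emulates the sampling design (3 regions × 2 parts × 6
animals; 36 biological samples), the published 11-carnitine marker
template (per-group mean ± SE), 2 LT-only and 17 KM-only extra
differential lipids, and 1050 null background lipids — 1080 in all — plus
3 pooled-QC injections (per-lipid overall mean with 5 % technical CV,
flagged `role="qc"`) so the QC stage runs end to end.

Marker abundances are zero-truncated normal per group. The per-sample
spread is derived from the template SE: σ = `noise_scale` · SE · √n, with
n the number of animals behind the reported value (6 for NX cells, 12 for
the pooled non-NX cells). Background lipids are log-normal with per-lipid
hyperparameters drawn once from log-mean U[9, 15], log-sd U[0.1, 0.4] —
spanning realistic peak-area magnitudes — and identical across groups, so
they carry no class signal. The within-group distribution family of peak
areas is not documented anywhere upstream; truncated normal for markers
and log-normal for background is an assumption, tagged in the
`NoiseModel`.

### Calibration of the planted design

The construction is required to make the screens recover exactly 13 LT
candidates, 28 KM candidates and an 11-marker intersection, and to plant
fold changes that clear the FC = 4 cut in ≥ 95 % of generations. Two facts
about the published template make that impossible verbatim:

1. Four knuckle-meat cells have printed NX/non-NX mean ratios *below* 4
   (CAR3 3.67, CAR5 3.70, CAR9 3.70, CAR10 3.90), although all 11 markers
   are reported as passing the cut in both parts. A template with a true
   ratio under 4 cannot reliably exceed 4 empirically.
2. At the SE-implied dispersion (noise_scale 1), the empirical log fold
   change at n = 6 has sd ≈ 0.19–0.45 per marker while the weakest margins
   are log(4.23/4) ≈ 0.06 — per-marker pass probabilities of 60–95 % and a
   joint recovery probability of a few percent.

The defaults therefore apply two calibrations, fixed from this margin
arithmetic before any end-to-end run and not revisited since: a
**planted-ratio floor** of 4.5 (any template cell below it has its non-NX
mean lowered to NX/4.5; every adjusted cell carries an `adjusted` flag),
and **noise_scale = 0.12**, at which the worst remaining margin clears the
cut with z ≈ 2.3 (≥ 99 % per cell). The price is realism: within-group
CVs land in the ~1–12 % range, technical-replicate-like rather than
biological. `noise_scale = 1.0` restores the SE-faithful dispersion and is
the basis of the deliberately hard `low_signal_spec` world (planted ratio
1.3) used for classifier comparison.

### What a green test does and does not establish

Green recovery tests establish that the screening, discriminant and
network machinery correctly extract a planted structure of the published
geometry from 1080-dimensional data at n = 36, including in the presence
of ~90 background lipids that pass the VIP cut by chance in a given part
(they are excluded by the volcano arm of the Venn, which is the point of
requiring both). They do **not** establish field performance on real
lipidomics data, where within-group dispersion is biological-scale,
classes are not exactly truncated-normal, lipids are correlated, and batch
effects exist; none of that is simulated. The published real-data
accuracies (97.2 % resubstitution, 94.4 % LOOCV, 100 %/100 % PSO-BP) serve
only as lower bounds that the clean synthetic world must meet.

## Known limitations

- Background lipids are mutually independent; real lipidomes have strong
  subclass correlation structure, which would lower the effective
  dimensionality of the null.
- The Fisher reference coefficients cannot be validated beyond the four
  published group-mean profiles.
- With population 5, GA and PSO are weak searchers of an 86-dimensional
  box; their benefit here comes mostly from multi-start plus burn-in
  selection. On a hard low-signal task both hybrids beat plain BP clearly
  on training fitness and on mean test accuracy, but distinguishing PSO-BP
  from GA-BP by *test* accuracy on 8-sample test sets is beyond the
  resolution of a 20-seed mean.
- The electronic-nose and volatile-compound branches of the original
  workflow, plot rendering, and subclass composition analysis are out of
  scope.
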