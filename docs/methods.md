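# Methods

## Data and the unit of analysis

The bundled table (`src/phylolat/resources/anthropoid_volumes.csv`)
transcribes the published per-specimen volumes (mL): whole brain and the
left/right posterior cerebellar hemispheres (PCH), frontal motor areas (FM)
and prefrontal cortex (PF) for 25 specimens from 16 anthropoid species. The
source text mentions 29 individuals while its printed table lists 25 rows;
the package carries exactly the printed rows and does not attempt to resolve
the discrepancy. Species are the unit of analysis: raw volumes are averaged
per species and then log10-transformed (mean-then-log; the log-then-mean
alternative is exposed via `species_means(average=...)`, and the log base is
configurable — log–log slopes are base-invariant, so nothing downstream
depends on it). Bilateral structure size defaults to left + right volume
before logging (`bilateral="sum"`); switching to the hemispheric mean shifts
intercepts by log10(2) and leaves slopes unchanged. Rest-of-brain (ROB) —
the allometric baseline — is brain volume minus all six structure volumes,
computed per individual and then averaged.

## Chronogram

No phylogeny accompanied the original data, so the package versions one
(`anthropoid_chronogram.nwk`, with the node-age table in
`anthropoid_node_dates.json`) built from the consensus anthropoid topology.
Four node ages are fixed by the divergence dates the source analysis states,
read as the onsets of the named ancestral branches: catarrhine crown 30 My
(start of the ape stem), hominoid crown 20 My (great-ape stem), gorilla
split 10 My (Homo–Pan stem) and Homo–Pan split 6 My (human terminal
lineage); the root (platyrrhine–catarrhine) is 46 My, the stated span of the
sample's divergent evolution. Remaining ages are literature-standard
consensus values chosen once: cercopithecoid crown 18, colobine split 13,
papionin–guenon split 11.5, guenon crown 9.5, patas split 8.5,
*Cercopithecus* split 6.5, platyrrhine crown 25 (pitheciid split), atelid–cebid
split 23, atelid crown 19, *Ateles*–*Lagothrix* 13. Every analysis accepts an
alternative Newick via `--tree`, so tree sensitivity can be assessed
directly. Polytomies are permitted and treated as hard. Branch lengths are
My throughout; all rates are per My.

## Regression engine

PGLS solves the GLS normal equations by Cholesky-whitening the covariance
and QR on the whitened design, which keeps the lambda = 0 (or star-tree)
case bit-comparable to OLS. Pagel's lambda multiplies off-diagonal
covariances only; it is profiled over [0, 1] with a 21-point scan plus
bounded Brent refinement (tolerance 1e-6), with both boundaries competing
with the interior optimum. The restricted likelihood is the default
objective (`reml=False` gives plain ML); lambda is re-estimated per
regression rather than shared across a battery. Slope and intercept CIs use
the t distribution on n − 2 df; lambda-estimation uncertainty is not
propagated into the CIs (standard practice, and the simulation suite
measures the consequence: 95% slope-CI coverage is exact when lambda is
known and ≈ 0.91–0.93 when lambda is estimated at n = 16).

The phylogenetic RMA slope is sign(r_GLS)·√(S_yy/S_xx) with GLS moments
taken about the GLS means; it equals the PGLS slope divided by |r_GLS| and
is undefined when |r_GLS| < 1e-12 (an error). Its slope CI follows the
classical major-axis construction applied to the GLS correlation; the
p-value is the t test of r_GLS = 0. Relative sizes are pRMA residuals of
log structure on log ROB with per-trait ML lambda; their GLS-weighted mean
is zero by construction.

## Laterality rule

Left and right hemisphere volumes are each scaled to log ROB by PGLS
(ML lambda), and a coefficient is flagged asymmetric when either
hemisphere's estimate lies outside the other's 95% CI, evaluated on
unrounded values ("either" rule); a stricter variant requiring exclusion in
both directions is exposed (`rule="mutual"`). CI-exclusion is not an exact
alpha = 0.05 test, so the suite measures its operating characteristics by
simulation at n = 16 under full Brownian residual signal: the either rule's
null flag rate is ≈ 0.25 (mutual ≈ 0.13), and power at a true slope gap of
0.5 is ≈ 0.99 and monotone in the gap. Users wanting a null rate ≤ 0.15
under strong phylogenetic signal should prefer the mutual rule.

## Branch rates

`ancestral_bm` gives ML Brownian ancestral states: each internal node is the
inverse-branch-length-weighted mean of its tree neighbors, solved as one
sparse linear system (equal to the Gaussian conditional expectation given
the tips, with the root at its GLS estimate). `ancestral_ap` is an
adaptive-peak variant allowing branch-specific rates: starting from the BM
solution it alternates (i) re-solving states with weights 1/(m_b·t_b) and
(ii) updating each branch multiplier toward |Δ_b|/t_b normalized to mean 1
(damped 50/50, floored at 1e-6), until the largest state change is below
`tol` (default 1e-8, `max_iter` 500, non-convergence is an error). This
iteration behaves like an L1/total-variation smoother: it concentrates
change onto few branches and collapses exactly to BM when multipliers are
pinned to one. A constant trait yields constant states and unit
multipliers. Mean-reverting (OU) dynamics are available in simulation only;
no OU fitting is performed.

Per-branch contrast measures change in excess of the allometric expectation
from ROB, with beta the clade-general PGLS slope of the trait on ROB. By
default the allometry-corrected trait log y − beta·log ROB is reconstructed
and its per-branch rate taken as the contrast; this is algebraically
identical to (Δy − beta·ΔROB)/Δt under the linear BM reconstruction, and for
the nonlinear adaptive-peak reconstruction it is the variant that localizes
lineage-specific shifts (an injected +0.3 log-unit branch shift is recovered
as the top flagged branch in ≈ 9/10 simulated datasets, versus ≈ 4/10 for
the raw-log wiring, whose multipliers lock onto the dominant allometric
signal). The raw-log wiring remains available
(`residualize_contrasts=false`). "Disproportionate joint increase" flags
branches where two traits' contrasts are both positive and both above their
own q-th percentile (default q = 0.75, configurable); the
prefrontal-over-motor shift score is the per-branch difference of PF and FM
contrasts, ranked among branches with positive PCH contrast.

## Synthetic data

`simulate_system` emulates the assumed generative structure: log10 ROB
evolves by BM from root value 1.9 (≈ 80 mL) with variance 0.0044/My —
spreading tips over roughly the observed 1.4-log-unit range on the 46-My
tree — and each structure × hemisphere log volume is intercept + slope·ROB
plus one draw from N(0, residual_sd²·C_lambda), where C_lambda is the
unit-diagonal tree correlation with off-diagonals scaled by lambda (a
lambda-weighted mixture of a Brownian deviation and independent noise, so
the simulated residual signal is exactly the lambda the fitting machinery
estimates). Defaults: slopes 1.6, intercepts −2.9 (structures a few percent
of ROB), residual_sd 0.1 log10 units, lambda 1 — values matching the
magnitude and signal of the real data. Hemisphere deviations are independent
by default (`hemi_corr` exposes a correlation), noise is multiplicative on
volumes (log-scale), branch shifts add log offsets to all descendant tips of
a named branch for chosen traits, and everything is seeded and
bit-reproducible. The generator does not emulate within-species sampling
variance, measurement error from histology, or hemisphere-correlated
measurement artifacts, so passing recovery tests speak to the estimators
under the assumed model, not to robustness against those features of real
data.

## Known replication limits

With the bundled chronogram the relative-size correlation battery reproduces
the originally reported R²/lambda pattern closely (e.g. 0.229 vs 0.24, 0.043
vs 0.04, lambda = 1 throughout; the right-PCH ~ left-FM value is the most
tree-sensitive, 0.374 vs 0.32). The hemisphere-specific ROB scaling slopes
do not reproduce at their reported magnitudes (≈ 1.5–1.8): on the printed
volumes the ratio of log-volume spreads caps any GLS/RMA log–log slope near
1.3, and this package obtains 1.05–1.30 under every fitting variant and
plausible chronogram. The qualitative laterality findings do replicate in
part: no PCH or FM asymmetry, left PF with a significantly lower intercept
and a steeper (though not CI-separable) slope than right PF. Branch-level
findings are model- and tree-dependent; robust across both reconstructions
here are the joint FM–PCH expansion on the ape ancestral branch (absent on
the human terminal branch) and positive prefrontal-over-motor shift scores
on the Homo–Pan ancestral branch and the human lineage.

## Problem sizes

The simulation studies in the test suite use the 16-tip chronogram with 500
replicates for slope-CI coverage and lambda recovery, 200 per condition for
laterality operating characteristics, 120 for the joint-flag null, and 5
replicate datasets for injected-shift recovery — sizes at which the
Monte-Carlo error is comfortably inside each assertion's margin.
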