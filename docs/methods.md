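# Methods

`thermoshift` implements two thermal-shift readouts for drug-target
deconvolution from TMT reporter intensities — the temperature-ladder
stability-score pipeline (2D-TPP) and the single-tube ramp pipeline
(STPP-UP) — together with the denaturation model and data simulator that
make both testable end to end. This note records the models, the defaults
and why they were chosen, and what the simulation-based tests do and do not
demonstrate.

## Denaturation kinetics

Soluble protein is modeled as a native state converting irreversibly to an
insoluble state with first-order Arrhenius rate k(T) = A·exp(−Ea/(R·T_K)),
R = 8.314 J/(mol·K), temperatures in °C at every interface and Kelvin
internally. Under a heating program T(t) the surviving soluble fraction is
S = exp(−∫ k(T(t)) dt): holds are closed-form, linear ramps are integrated
by adaptive quadrature (absolute tolerance well below 1e−9; the simulator
uses an equivalent 64-node Gauss–Legendre rule, vectorized over proteins).
Because the process is memoryless and irreversible, survival is exactly
multiplicative over program concatenation and monotone in exposure — both
asserted by tests. This is the simplest model in which losses accumulated
along an incremental ramp persist to the end of the program, which is the
premise of the single-tube readout. Reversible and multi-state unfolding,
aggregation kinetics, and ligand-binding thermodynamics are out of scope.

`calibrate_kinetics(tm50, Ea)` solves A in closed form so that a 3-minute
hold at `tm50` leaves exactly half the protein soluble, i.e. the isothermal
melting curve sampled at 3-minute exposures has its 50% point (the T_m-50,
referenced to the lowest ladder temperature) at the requested value.

**Default activation energy: Ea = 550 kJ/mol.** Ea controls the width of
the melting transition and, through it, how a continuous ramp maps onto an
equivalent isothermal hold. The default is calibrated so that, for a
protein with the mammalian-average T_m-50 of 51 °C, the standard ramp
(5 s at 37 °C, then 37→57 °C at 0.2 °C/s) denatures as much protein as a
3-minute hold at ≈52 °C — the ramp/hold equivalence observed
experimentally. The value sits in the upper part of the published range for
irreversible protein denaturation near the melting point and yields a
melting transition ≈6 °C wide, comparable to measured proteome-wide melting
curves. Lower values (e.g. 250 kJ/mol) produce visibly shallower curves and
an equivalence temperature near 48.8 °C, inconsistent with the observed
calibration. Ea is configurable everywhere, with per-protein jitter in the
simulator (σ = 25 kJ/mol, truncated positive).

`isothermal_equivalent_temperature` inverts the survival of an arbitrary
program into the temperature of an equally destructive reference hold by
bracketed root finding on [0, 100] °C (xtol 1e−4 °C); it errors when
survival is 0 or 1. Melting curves are fitted with a descending sigmoid
f(T) = (1−plateau)/(1+exp(steepness·(T−midpoint))) + plateau by bounded
trust-region least squares from a fixed multi-start grid (deterministic);
flat or rising data yield a flagged-failure result rather than an
exception. T_m-50 extraction from a fitted curve is closed-form, with an
explicit error when the 50% level lies at or below the plateau.

## Simulator

Each simulated protein draws a T_m-50 (Normal(51, 4) °C, clipped to the
calibratable range), an activation energy, a base reporter intensity
(log-normal, log2-mean 20, log2-sd 2 — a plausible corrected-reporter
scale), a unique-peptide count (2 + Poisson(4), so an unfiltered proteome
passes the two-peptide rule), and a non-melting plateau fraction, uniform
on [0.02, 0.12]. The plateau mirrors the high-temperature plateau of real
melting curves (aggregation-resistant fraction plus ratio-compression
floor); without it the pure kinetic model drives survival to ~1e−20 at the
top of the ladder, every channel collapses to the noise floor, and
abundance-only proteins acquire large spurious stability scores — the
opposite of observed behavior.

Planted effects: stabilized/destabilized targets shift the treated
condition's T_m-50 by ΔT_m exactly (A recalibrated at fixed Ea), and
abundance effects multiply all treated channels by 2^Δlog2FC independent of
heating. `pinned_tm50` fixes chosen proteins' melting points so benchmark
targets sit at a known point of the melting range; recovery rates then
measure statistical power rather than the heating program's dynamic range
(a target melting far above T_max is physically invisible to a ramp — a
documented limitation of the method, not of the pipeline).

Measurement error is two-component: mean-one multiplicative log-normal
noise with coefficient of variation `cv` (default 0.1) on the signal, plus
an additive floor drawn per measurement from Normal(1024, 512) clipped at
zero (≈0.1% of the median base intensity). This is exactly the error
family the generalized-log transform is designed for; a noise-free constant
floor would produce near-zero-variance measurements for fully denatured
proteins and corrupt the empirical-Bayes variance prior. Missing values are
written as 0 (the MaxQuant convention) with configurable probability. The
noise magnitudes are documented defaults, not estimates from any real
dataset.

Layouts: TPP (one plex per ladder temperature, conditions × replicates
within, capacity 10), STPP-UP (one 16-plex holding test-ramp and 37 °C
control channels for every condition × replicate), isothermal hold (same
plex structure with a constant-temperature test). The default ladder is
37, 40.4, 44, 46.9, 49.8, 52.9, 55.5, 58.6, 62, 66.3 °C; the published
protocol table contains an out-of-order 68.6 °C entry that is almost
certainly a transcription error for 58.6 °C, and the verbatim ladder
remains available behind a flag. Tables round-trip losslessly through a
MaxQuant-proteinGroups-like TSV dialect, optionally with injected decoy /
contaminant / site-only rows for filter testing.

## QC filtering

Rows are removed in a fixed order — decoy/contaminant/site-only flags,
then unique peptides < 2, then (by default) lack of a strictly positive
signal in every mapped channel — with each row attributed to the first
rule that removes it. Only the attribution depends on the order; the
surviving set does not. Filtering is idempotent and the per-rule counts
partition the input exactly. Whether the completeness rule ran before or
after normalization was left open by its source description; it is applied
first here, which keeps the normalization input complete.

## Variance stabilization

Channel c is transformed as h_c(x) = glog2((x − a_c)/b_c) with
glog2(y) = asinh(y)/ln 2; a_c is the background offset and b_c > 0 the
channel scale. Within each normalization group the parameters are fitted
by the profile likelihood of the calibrated model h_c(x_ic) = μ_i + ε:
(M/2)·log RSS minus the transformation log-Jacobian, over the best 90% of
proteins (least-trimmed squares, re-selected three times; trim fraction
configurable). The Jacobian term is essential — plain least squares on
transformed values is degenerate, since inflating every scale flattens all
channels to zero residuals. Offsets are capped below the smallest observed
intensity per channel: the background is only weakly identified in bright
channels and the cap prevents the Jacobian term from drifting the offset
into the data and crushing the dimmest proteins. After the fit, channel
scales are adjusted along the (near-flat) joint-scale direction so that
transformed channel medians within each group agree exactly (solved on the
central order statistics). On two-component noise the transform drives the
SD-versus-mean Spearman correlation to ≈ −0.06 ± 0.03 (plain log2: ≈ 0.3).

Grouping: ladder data are normalized per temperature (signal composition
changes drastically up the ladder); single-tube data per heating role
(ramped test channels together, 37 °C controls together) for the same
reason — a single group would mix a half-denatured and an intact proteome
and break the calibration. The fit is deterministic given the input.

Note the fit is only identified when measurement noise is present:
noise-free data give zero residuals for any parameters, and the Jacobian
term then dominates pathologically. Exact-arithmetic tests therefore score
log2 data directly.

## Batch effects

`remove_batch_effects` fits, per protein, intensity ~ condition + batch
(sum-to-zero batch coding) and subtracts the fitted batch component,
preserving condition contrasts exactly in balanced designs; confounded
designs (a batch missing a condition) are rejected. A single batch is the
identity.

## Moderated testing

The two-sample test uses the pooled equal-variance estimate and shrinks
per-protein variances toward a prior via the scaled-F model
s² ~ s₀²·F(d, d₀), with (d₀, s₀²) from the closed-form moment-matching
estimator on log s² (digamma/trigamma matching; the trigamma equation is
inverted by Newton iteration). The implementation is verified against a
limma `eBayes` fit run through Rscript on a shared fixture. Moderated
t = log2FC/(s̃·√(1/nA+1/nB)) on d₀+d df (normal when d₀ = ∞), two-sided
p, Benjamini–Hochberg adjustment. `prior_df=0` recovers the ordinary
t-test exactly. A one-sample variant serves the ladder pipeline's
replicate-score test.

Two extensions, both off by default and enabled by the single-tube hit
caller: an intensity-dependent prior (log s² detrended against mean
transformed intensity with equal-count-bin means, the limma-trend
analysis) because variance rises steeply toward the reporter noise floor;
and pooling of within-cell residuals from additional design cells into the
variance estimate (the single-variance linear-model fit over the whole
design that a limma/DEP analysis performs), which raises the residual df
from 4 to 8 in the standard 3-replicate single-tube design.

## Score-based FDR

Stability scores are robustly z-transformed (median/MAD). The null scale
is estimated from the central 75% quantile band of |z| by matching the
band edge to the corresponding half-normal quantile — consistent for a
normal null and, unlike a truncated MLE, insensitive to mild shape
mismatch in the bulk (a 20% scale error changes far-tail FDRs by orders of
magnitude). The null fraction eta0 is the band count over the band's null
mass, capped at 1. Reported per protein is the tail-area FDR
eta0·P0(|Z| ≥ |z|)/P̂(|Z| ≥ |z|), clipped to [0, 1] and made monotone
non-increasing in |z| by a conservative running maximum from the largest
|z| downward. At least 50 finite scores are required; a zero MAD is an
explicit error.

## Single-tube readout

After role-grouped variance stabilization, the control-batch log2 fold
change (treated minus untreated 37 °C channels) is added to the untreated
test channels, replicate-matched by default: each replicate's own control
difference corrects its own test channel, so the sampling noise of the
correction appears in the within-group variance where the moderated test
can see it. (Adding the replicate-mean difference uniformly — available
via a flag — shifts the contrast by an error invisible to the variance
estimate and inflates null t-statistics by ≈√2; measured on null
simulations it produces ~2 false hits per 2000 proteins where the
replicate-matched form produces ~0.) The moderated contrast of treated vs
corrected-untreated test channels then yields hits at |log2FC| > 0.5 and
BH-adjusted p < 0.001 (both configurable; the looser adjusted p < 0.05 of
the protocol text is exposed in config as well — the two published
descriptions disagree and the volcano-plot threshold is the default).

A hit is flagged **correction-driven** when its control-batch fold change
Δ opposes the corrected fold change in sign and |Δ| ≥ θ·|log2FC| with
θ = 0.5: a negative Δ manufactures apparent positive enrichment, so such
hits are "mostly" the correction rather than thermal stabilization. θ
quantifies a qualitative published description and is configurable.

## Ladder readout

Per replicate and ladder temperature, the treated-minus-untreated
transformed intensity difference forms a fold-change profile. The
abundance score is the mean log2FC at the two lowest temperatures
(37, 40.4 °C); the stability score is Σ_T (log2FC_T − abundance score)
over the whole ladder — exactly zero for any constant profile, linear in
the profile, and invariant to adding constants. Scores are computed per
replicate (averaging after scoring preserves variance information), the
replicate scores are tested against zero with the moderated one-sample
machinery, and the replicate-mean scores receive the tail-area FDR.
Classification: "hit" at score > 3 and FDR < 0.01, else "candidate" at
score > 2 and FDR < 0.05, else "none"; hit takes precedence. The published
thresholds are one-sided in the stabilized direction and are applied as
stated.

## Benchmark conditions and what they show

The acceptance benchmarks simulate 2000 proteins with one stabilized
target (ΔT_m = +4 °C, pinned at T_m-50 = 51 °C) and twenty abundance-only
decoys (log2FC = ±1), cv = 0.1 — three replicates for the single-tube
layout, two for the ladder, twenty simulation seeds each. Under these
conditions the single-tube readout recovers the target as the top
unflagged hit in ≈97% of runs with no unflagged decoy hits and a clean
null (0 hits per 2000-protein null run); the moderated test's global-null
type-I error is within [0.035, 0.065].

The ladder readout classifies the target as a hit in ≈70–85% of runs. The
limiting arithmetic is worth recording: at two replicates and cv = 0.1 the
null stability-score sd is ≈0.91 (the abundance-score subtraction
contributes most of it), so a tail-area FDR < 0.01 among 2000 proteins
requires a score ≳4.3, while the target's deterministic score ranges over
≈4.4–7.7 depending on its plateau draw. High-plateau draws therefore sit
at the decision boundary and noise decides them. The companion check —
abundance decoys classified "none" — passes in ≥95% of runs. These are
statements about this generator; real data add peptide-level effects,
co-isolation interference, and batch structure that the simulator
deliberately omits, so passing benchmarks demonstrate correctness of the
statistical machinery, not performance guarantees on real experiments.

## Numerical choices and degenerate inputs

Quadrature tolerances as above; melting-curve fits are deterministic
multi-start; the glog fit is L-BFGS-B with analytic gradients and fixed
iteration caps; BH and the FDR monotonicity repairs are exact
accumulations. Degenerate cases are explicit: empty heating programs,
non-finite kinetics, overfull plexes, confounded batch designs, groups
with one channel, all-zero groups, zero-MAD score vectors, and unreachable
50% levels all raise typed errors; flat melting data return flagged
failures. Survival underflow at extreme temperatures flushes to exactly
0.0, which downstream code treats as a legitimate value.

## Reproducibility

Every stochastic step takes a single integer seed; the CLI derives
per-stage seeds from the configured seed with a fixed counter scheme, so
adding a stage does not perturb earlier ones, and identical configs give
byte-identical outputs. Run metadata (config hash, seed, package versions)
is written alongside every pipeline output.
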