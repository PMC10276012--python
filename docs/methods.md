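# Methods

## Scope and data model

The package analyses pulsed swimming of scyphozoan medusae from digitized
bell-apex trajectories: time series of apex coordinates (cm) with optional
bell height/diameter series and water temperature. Units are cm and s
everywhere; SI conversion happens only inside the Reynolds computation.
Columns in all I/O are unit-suffixed (`u_cm_per_s`, `t_s`, ...) to prevent
cm/m confusion.

## Instantaneous kinematics

Fineness `f_i = h_i/D_i` is per frame; displacement, velocity and Reynolds
number are interval quantities (length n−1). For Re the per-frame diameter
is averaged over the interval's two endpoint frames — symmetric and
unbiased for smooth D(t). Kinematic viscosity defaults to a three-point
seawater table {15 °C: 1.17e-6, 20 °C: 1.05e-6, 25 °C: 0.95e-6 m² s⁻¹}
with linear interpolation, clamped at the endpoints; an explicit
`viscosity` argument overrides. Sequences missing bell dimensions (e.g.
literature-extracted tracks) get NaN fineness/Re but full velocity
metrics.

Two optional preprocessing steps, recorded in output metadata, run before
differentiation: uniform resampling to a user dt (real digitizations are
often made at intervals of minimal body movement rather than every frame)
and a centered moving average of the positions (window in samples,
default off).

## Pulse-cycle detection and phase segmentation

Velocity peaks are local maxima of the (optionally smoothed) velocity
with prominence ≥ α·(p95 − p5 of u), α = 0.25 by default, height ≥
p5 + 0.5·(p95 − p5), and separation ≥ half the median inter-peak spacing.
The height floor matters: the passive-energy-recapture bump is itself a
local maximum, but sits in the lower part of the velocity range, while
the contraction peak reaches the top of it.

Each cycle starts at the onset of contraction — the **rightmost** sample
attaining the pre-peak velocity minimum. The rightmost convention is
deliberate: on a flat coasting trough every sample ties for the minimum,
and only the last one marks where the velocity actually begins to rise.
When fineness is available the start is refined to the last
fully-relaxed-bell frame before the peak (both velocity and fineness
profiles carry the phase structure). Contraction ends at the velocity
peak; relaxation ends at the first maximum-diameter frame after the peak
(minimum fineness as proxy; earliest index wins ties); the interpulse is
the remainder. With no bell series at all, relaxation ends at the
post-peak velocity minimum and the cycle is flagged
`fallback_velocity_only`. Phase times are timestamp differences and phase
distances are sums of m over half-open index spans, so the three phases
partition each cycle's duration and displacement exactly.

Smoothing-bias correction: a symmetric smoothing kernel (moving averages
of positions and/or velocity) displaces the maximum of an asymmetric peak
toward its flatter flank — for a pulse whose rise is faster than its
decay, the detected peak drifts late and contraction time inflates. Since
the kernel is known, the displacement has a closed form for a locally
two-sided-quadratic peak: the smoothed maximum sits where
`B_l·m⁻(t) = B_r·m⁺(t)` with B_l/B_r the flank curvatures and m∓ the
kernel's one-sided first moments. The curvature ratio is estimated as
(R̄/C̄)² from the segmentation's own phase durations (curvature of a
smooth arch scales as 1/width²) and the correction is iterated so the
ratio is computed from corrected durations. The sub-sample remainder of
the shift adjusts the contraction/relaxation split in time without moving
indices, preserving the partition identities. The correction is on by
default and inert when no smoothing was applied.

Metrics: P_time, P_dist and phase means are across-cycle averages;
P_freq = n_pulses / elapsed time, reported only for ≥ 2 pulses (NaN
otherwise), with 1/mean(P_time) carried as an alternative (identical for
contiguous start-to-start cycles); PER = mean(I_dist)/mean(P_dist), with
the mean per-cycle ratio as an alternative; u_max/Re_max average each
cycle's maximum. The reference diameter of a sequence is the mean over
cycles of the per-cycle maximum diameter (the fully relaxed bell) and is
the size variable used by the scaling stage.

## Synthetic pulsed swimmer

The generator is first-class, tested code: it defines the conditions
under which every downstream stage is validated. Within each cycle of
period 1/pulse_freq, speed follows raised-cosine ramps — trough to peak
over the contraction fraction, peak back to trough over relaxation, and a
raised-cosine bump of amplitude `interpulse_gain · peak_velocity` over the
interpulse (the PER signature). Raised cosines are C¹ at phase boundaries
with unambiguous extrema, so no spurious peaks confound segmentation, and
they integrate in closed form: `analytic_metrics` returns the exact phase
times, distances, PER and cycle-average speed implied by any parameter
set, which is the ground truth the recovery tests compare against.

Fineness runs antiphase to speed (relaxed → contracted over contraction,
back over relaxation, flat at relaxed during the interpulse); diameter
follows from fineness under a conserved subumbrellar-volume proxy
(h·D² constant), so h/D recomputes the schedule exactly and the maximum
diameter marks the relaxation/interpulse boundary. Swimming is along a
straight heading — real medusae turn, but straight paths make the
displacement decomposition exact for testing. Positional noise is iid
Gaussian jitter per coordinate; the bell series stay noiseless (they
model morphometry, not tracking error — a known idealization). Defaults
(2.5 Hz, 30/45/25% phase split, peak 3 cm/s, trough 0.5 cm/s, gain 0.15,
2 cm bell, fineness 0.5–0.8) sit in the range reported for mid-sized
discomedusae; the interpulse bump magnitude is not constrained by
published profiles, so it is a free parameter rather than a fixed value.
Seeds are explicit arguments everywhere; no global random state.

What passing recovery tests show is that the segmentation recovers the
schedule of this idealized swimmer (including under 2% positional jitter
with several sequences averaged, as real studies average repeated
recordings); they do not certify performance on turning animals, noisy
bell tracking, or non-stationary pulsing.

## Ontogenetic scaling and allometric normalization

Four families are fit by OLS in their transformed spaces: linear (y~x),
log-linear (y~log x), power (log y~log x) and exponential (log y~x) —
spanning the monotone shapes kinematic traits show against bell diameter.
Families are compared by BIC on the *original* response scale: the log-y
likelihood gets the log-Jacobian term (−Σ log y), since raw-y and log-y
BICs are otherwise incomparable. k = 3 (two coefficients + error
variance). The error variance is floored at (1e-10·sd)² so exact fits
stay finite; near-ties (< 1e-9) resolve to the earlier family in the
candidate order. Shapiro–Wilk (scipy) is exposed to motivate log
transforms. Group-wise fits (order/family cofactors) return 95% CI bands
on the mean response, back-transformed for log-y families; groups under
4 points are omitted with a warning.

Normalization takes residuals from the best-BIC regression pooled over
**all** records, in that model's transformed response space, and averages
them per species (unweighted arithmetic mean). When the pooled slope is
not significant (p > 0.05) residuals reduce to centered trait values —
the intercept-only regression — so species means remain size-free. OLS
with intercept guarantees the record-weighted grand mean of residuals is
zero.

## Ordination

Pearson correlations use pairwise deletion with two-sided p from the t
transform (n−2 df); pairs with < 3 complete rows or zero variance are
NaN. PCA standardizes traits (correlation-matrix PCA) by default because
the traits mix units (s, cm, Hz, dimensionless); rows with missing values
are dropped listwise. Component signs are fixed so each loading vector's
largest-magnitude entry is positive, making outputs reproducible.
Explained-variance fractions are recomputed from the component variances
so they sum to 1 exactly.

## Phylogenetic comparative analysis

Trees are consumed as rooted Newick with branch lengths (dendropy behind
the module surface); tree inference is out of scope. Non-ultrametric
trees are accepted throughout. Zero-length branches are replaced by
1e-8 × tree depth (with a warning) so C stays invertible; duplicate tips
and missing lengths are errors (a default length option exists). Pruning
to a taxon subset suppresses unifurcations and sums branch lengths,
preserving patristic distances.

C[i,j] is the root-to-MRCA shared path length; the diagonal holds
root-to-tip depths. Blomberg's K is computed from C by dense Cholesky
algebra:

    â = (1ᵀC⁻¹x)/(1ᵀC⁻¹1)
    K = [(MSE₀/MSE)] / [(tr C − n/(1ᵀC⁻¹1))/(n−1)],
    MSE₀ = (x−â)ᵀ(x−â)/(n−1),  MSE = (x−â)ᵀC⁻¹(x−â)/(n−1)

K ≈ 1 under Brownian motion, → 0 for phylogeny-independent traits. The
randomization test shuffles trait values across tips (vectorized: one
Cholesky factorization serves all permutations) and uses the add-one
estimator p = (1 + #{K_perm ≥ K_obs})/(n_perm + 1), so p is never 0;
default 1000 permutations, seed mandatory in the CLI. K is invariant to
affine trait transforms and to rescaling all branch lengths, which the
suite checks, along with agreement to 1e-8 with a dense explicit-inverse
oracle and an independent R/phytools cross-check.

Ancestral states are the BM maximum-likelihood (GLS) estimates: the root
is the phylogenetically weighted mean â, and each internal node's state
is â + sᵀC⁻¹(x − â1) with s the vector of node-to-tip shared path
lengths — equivalently the weighted mean after re-rooting at that node
(verified against a re-rooting oracle and phytools' fastAnc). States are
interpolated linearly along each edge at a configurable grid (default 10
points/edge) for trait mapping; linear interpolation approximates the
finer ML interpolation used by contMap-style plots.

## Pipeline

`run_pipeline` chains trajectories → kinematics → segmentation →
per-sequence metrics → scaling fits → normalized species table →
correlations/PCA → K and ancestral states, writing each stage as plain
CSV/TSV plus a manifest, a log (with per-sequence cycle counts and
fallback flags for auditing) and an echoed YAML config. Stages re-run
from intermediates; with a fixed seed the whole run is bit-reproducible.
The packaged 17-taxon tree carries the species names of well-studied
scyphozoans on a synthetic topology with invented branch lengths — a
fixture for tests and examples, never an inferred phylogeny.

## Problem sizes and numerical choices

Recovery studies use 12-cycle swims sampled at 100 points per cycle,
with a 3×3×3 grid over pulse frequency (1/2.5/4 Hz), contraction
fraction (0.2/0.3/0.4) and interpulse gain (0/0.15/0.3); noisy runs
average 3 sequences. Calibration uses 1000 Brownian replicates on the
17-taxon tree, 1000 white-noise replicates and 500 null datasets ×
199 permutations on a deep balanced 16-tip tree. BIC selection uses 100
datasets of n = 200 with lognormal noise (sd 0.1) around a D^0.8 power
law. These sizes keep the full suite and the acceptance script in the
seconds-to-minutes range while leaving Monte-Carlo error well inside the
asserted bands.

## Known limitations

2D trajectories only; no body-orientation, bell-margin or wake/vortex
quantities; no fluid-dynamics simulation. No PGLS or signal statistics
beyond K (no Pagel's λ); no stochastic character mapping. The
segmentation assumes one dominant velocity peak per cycle; strongly
irregular pulsing or PER bumps taller than half the velocity range would
require retuning the detection fractions. The interpretive question of
what K "strong signal" means at small n is left to the user: the module
reports K and p without encoding a threshold.
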