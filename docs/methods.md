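# Methods

This note documents the models, rules, and numerical choices behind
`hiveflow`, and what the synthetic-data experiments do and do not show.

## Coordinate conventions and units

Positions are barcode centers in millimetres, origin at the hive's
upper-left corner with y increasing downward (the screen convention of
tracking imagery). Frames are 0-based integers sampled at `fs` frames per
second (default 1, the recording rate of the tracking system the package
targets). Orientations are body-axis angles in [0°, 360°). All thresholds
live in `PipelineConfig` and are never hard-coded at call sites.

## Kinematics

Linear speed is the Euclidean displacement of the barcode center between
consecutive frames divided by the inter-frame interval 1/fs. (The rate
enters as a division by 1/fs rather than by fs itself so that speed carries
units of distance/time; at fs = 1 the two readings coincide.) Angular speed
is the unsigned angle between the orientation vectors, wrapped to
[0°, 180°], over the same interval. Two suppression rules apply:

* no measurement for frame t+1 if the bee was undetected at t — pairs
  spanning a detection gap are never interpolated;
* `recorded = False` (both speeds absent, not zero) when displacement
  < 4.9 mm **and** turn < 60°: sub-cell motion is what a stationary bee
  produces while grooming or being groomed. When either threshold is
  exceeded, both speeds are recorded, keeping the linear and angular sample
  sets aligned.

Mean speeds average the recorded measurements inside the analysis window;
a bee with no recorded measurement gets an absent value.

## Trophallaxis events

Raw detector fragments of the same unordered pair are merged transitively
when the gap between one fragment's end and the next's start is < 60 s;
overlaps are unioned. Durations use the inclusive frame span, (end − start
+ 1)/fs, so a single-frame event at 1 frame/s lasts 1 s. Merged events
shorter than 3 s (no plausible liquid transfer) or longer than 180 s
(spurious detection) are dropped; both boundaries are inclusive on the keep
side. The sociability score counts each surviving event once for each
partner, assigns events to the analysis window by start frame, and divides
by the window length in days, yielding events/day. The per-day
normalization (rather than per detected time) is a deliberate choice; the
conservation identity Σ_bees frequency × days = 2 × events is re-checked at
run time.

## Proximal interactions

For every ordered (focal, neighbor) pair, maximal runs of contiguous frames
are extracted in which (i) both bees are detected, (ii) their distance is
≤ R_max = 20 mm (about twice a body length), (iii) neither bee is in a
low-speed frame, and (iv) the pair is not inside one of its own filtered
trophallaxis events (trophallaxis with third parties does not exclude).
"Low speed" reuses the kinematic stationarity rule — a frame whose incoming
pair produced `recorded = False` — instead of introducing a second
threshold. Excluded frames break contiguity, because the VAR estimation
downstream assumes gap-free uniformly sampled series. Runs of ≥ L_min = 30
frames become interactions and are kept whole, not truncated; when a focal
bee meets the same neighbor repeatedly, only the earliest interaction is
kept, so neighbor identity varies across a bee's interactions. Every bee
serves as focal, so one physical encounter can contribute to both bees'
estimates.

## VAR estimation

Each interaction contributes one bivariate series per axis: (focal
coordinate, neighbor coordinate), raw values, mean-removed, not differenced
(a differencing switch exists for stationarity-sensitive users). The VAR is
fitted by conditional least squares without intercept. The innovation
covariance uses the degrees-of-freedom corrected denominator T − k·p
(T = n − p regression equations, k·p regressors per equation). Automatic
order selection minimizes the multivariate AIC, ln det Σ̂_ML + 2k²p/T, over
p ∈ {1..3} on a common effective sample; the cap of 3 keeps at most 12
coefficients against the 60 data points of a minimal 30-frame interaction.
Constant or rank-deficient series raise an error naming the interaction;
a focal bee whose interactions all fail yields an absent influence value
with diagnostics rather than a silent zero.

## iPDC and information flow

With Ā(f) = I − Σₘ Aₘ e^(−i2πfm/fs) and ā_j its j-th column, the squared
information PDC for direction j → i is

    iPDC²(f) = |Ā_ij(f)|² / ( Σ_ii · ā_j(f)ᴴ Σ_w⁻¹ ā_j(f) ).

Two properties pin this normalization down: it reduces exactly to the
squared generalized PDC whenever Σ_w is diagonal, and it is bounded in
[0, 1] for *every* symmetric positive-definite Σ_w — by Cauchy–Schwarz in
the Σ_w⁻¹ inner product, |e_iᵀā_j|² ≤ Σ_ii · (ā_jᴴΣ_w⁻¹ā_j), with equality
attainable (ā_j ∝ Σ_w e_i), so the bound is tight. Boundedness is what
makes the integrand below well-defined; a per-partial-variance weighting
([Σ_w⁻¹]_ii in the numerator) was considered and rejected because it
exceeds 1 for correlated innovations. The test suite re-verifies
boundedness on 1,000 random stable VAR(1..3) models with random SPD
innovation covariances. Classic PDC (`variant="euc"`, column-norm
normalization, Σᵢ|π_ij|² = 1) and gPDC (`variant="diag"`) are provided for
comparison; `"info"` is the default used by the pipeline.

Spectra are evaluated on 128 uniform frequencies spanning [0, fs/2]
inclusive; all interactions share the grid so pointwise averaging is
well-defined. Information flow integrates −log₂(1 − iPDC²) over the grid by
the trapezoid rule and divides by fs. Values are clipped to 1 − 1e−12
before the logarithm (floating-point boundary safety; the integral is
unchanged at reporting precision); values above 1 beyond 1e−6 raise, since
they indicate a formula or fit error, not noise. Doubling the grid changes
the result by < 1e−3 bits on the models tested. The averaging order follows
the pipeline's definition exactly: average spectra across interactions per
axis, integrate each averaged spectrum, then average the X and Y flows into
the single per-direction value per bee.

## Behavioral states

Forager: ≥ 6 trips total, ≥ 2 distinct days with ≥ 4 trips (the reading of
"more than three trips per day, for any 2 days"; the days need not be
consecutive), and ≥ 25% of *all* trips starting within peak hours
10:00–15:00, bounds inclusive. Aggression sums biting and stinging;
brood care is larval feeding; inspection, fanning, wax-building and
vibration count toward responsiveness only. The consistency criterion
"≥ 20–30 s" is resolved to a single configurable threshold defaulting to
the permissive 20 s. Assignment order: ≥ 2 qualifying behaviors
(aggression, care, foraging) → generalist; otherwise the single qualifying
behavior names the specialist; zero activity of any kind and no foraging →
non-responder; any remaining activity below threshold → baseline. The six
labels are exhaustive and mutually exclusive by construction; a bee missing
from the assay table is returned unlabeled with a diagnostic.

## Association statistics

The polygenic score is Σ_s dosage[b,s]·β[s] with dosage the count of
alternative-allele copies (the alternative allele is the effect allele,
matching the convention in which the low-sociability genotype is homozygous
alternative). The overlap test reports k = |A∩B|, fold enrichment
k/(|A||B|/N), and the upper-tail hypergeometric probability P(X ≥ k)
including the observed overlap, with optional Bonferroni adjustment capped
at 1 (via `scipy.stats.hypergeom`; tests verify it against exact
integer-arithmetic enumeration). Group comparisons delegate to
`scipy.stats` and statsmodels' Tukey HSD; ranks use midranks under ties.
Degenerate inputs (a group with < 2 observations, all values identical)
raise instead of returning NaN statistics.

## Synthetic colony generator

The generator's job is to produce inputs with the statistical structure the
analysis assumes, with every injected signal logged as ground truth.

**Movement.** Each bee's per-frame displacement follows a stable AR(1)
process, d(t) = 0.5·d(t−1) + η(t), η ~ N(0, 6² mm²) per axis, plus a weak
pull (0.02/frame) toward the hive center that emulates comb clustering.
This puts typical walking displacements at 8–12 mm/frame — an actively
walking bee, comfortably above the 4.9 mm stationarity threshold. A coupled
follower additionally receives c times the leader's realized displacement
at t−1, so a (leader, follower) pair is exactly a bivariate VAR on
displacements and the influence target is identifiable. Positions reflect
at the walls (windows rarely touch them); body orientation follows the
displacement direction. The AR(1)-velocity form is a modelling convenience
for identifiability, not a claim about bee locomotion.

**Stationary and trophallaxis bouts.** Stationary bouts (entry probability
0.01/frame, mean 30 frames) and trophallaxis episodes (default 1 raw event
per bee-hour, mean 20 s) freeze the bee at an anchor with uniform ±1 mm
jitter and ±10° heading jitter — below both kinematic thresholds — and
trophallaxis partners sit 5 mm apart, inside the detector's 1.7–7.4 mm
contact geometry, so the exclusion rules have real work to do. Raw event
tables are produced by fragmenting each injected episode into detector-like
pieces with sub-minute gaps, which the merge rule must reassemble exactly.

**Co-walk episodes.** A qualifying proximal interaction requires two bees
to stay within 20 mm for 30 consecutive frames while both move
supra-threshold. Independent random walkers essentially never do this —
their relative position diffuses as fast as they walk — and in real
colonies such episodes are following/co-walking behavior, i.e., correlated
motion. The generator therefore injects explicit co-walk episodes (default
8 per bee-hour, mean 90 s): both bees follow a shared smooth flow
(speed ≈ 8 mm/frame, slowly turning heading) plus small individual AR(1)
jitter and a weak spring that keeps the pair near 10 mm apart. Episode
partners are drawn with a least-scheduled-first balance so coverage spreads
over the colony; episodes are logged in the ground truth. Outside these
episodes bees move independently, so displacement cross-correlations
between uncoupled bees remain near zero.

**Detections.** Each (bee, frame) is dropped independently with probability
0.02, in the range of per-frame barcode miss rates for this kind of
imagery. Dropout is the binding constraint on interaction yield (a clean
30-frame run of joint detections has probability 0.96³⁰ ≈ 0.3 per aligned
window), which is why episode durations comfortably exceed 30 s.

**Trips, assays, genotypes.** Trip logs give designated foragers patterns
satisfying every clause of the forager rule and other bees patterns
violating a recorded clause (too few trips, one qualifying day, or
off-peak timing); non-responders take no trips. Assay tables realize each
intended label's defining durations, including sub-threshold responses plus
a fanning/wax/vibration record for baseline bees. Genotypes are
Binomial(2, maf) dosages with maf ~ U(0.05, 0.5); the ground-truth
polygenic score is computed by an explicit double loop, independent of the
vectorized implementation it validates.

**What passing tests do not show.** The generator realizes the assumed
structure cleanly: no barcode identity swaps, no spatial heterogeneity
beyond central clustering, movement that is exactly low-order
autoregressive, and co-walks with a known shared flow. Results on real
tracking data can differ by calibration offsets — in particular the
absolute scale of information flow depends on the (unknown) estimator
settings and movement spectra of real bees, so synthetic flows (~0.1 bits
on 30-frame windows) are not comparable to colony-scale values, and the
pipeline's validated claims are about *relative* structure: null symmetry,
monotonicity in coupling strength, and rule-exactness.

## Problem sizes

The packaged demonstration colony uses 20 bees for 2 simulated hours
(7,200 frames) in a 120 × 70 mm arena — a bee density comparable to a
crowded comb section, chosen so that every bee accumulates proximal
interactions within the short window. Estimator benchmarks use 20 random
stable VAR(2) models fitted at 10,000 samples; null symmetry uses
200–2,000 uncoupled pairs on 30-frame windows (the pipeline's window
length); directional recovery uses 100 replicates at each coupling
c ∈ {0, 0.2, 0.4, 0.6}. At these sizes the full suite runs in well under a
minute.

## Known limitations

* No asymptotic confidence intervals or significance tests for PDC; only
  point estimates and replicate-level summaries.
* Bivariate conditioning only — influence is pairwise, not conditioned on
  the rest of the colony.
* Raw coordinates are near-integrated over 30-frame windows; the VAR fit
  is short-memory on a near-unit-root series, which biases absolute flow
  upward symmetrically (the null-symmetry benchmark quantifies this).
* The trip-pass merging that produces the trip table from raw entrance
  camera passes is upstream of this package; trips are consumed as given.
* Per-bee interaction coverage in the demonstration colony is
  probabilistic; at its deliberately small scale a bee can occasionally
  end a window without a qualifying interaction and is then reported with
  an absent influence value.
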