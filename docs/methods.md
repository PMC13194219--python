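# Methods

## Study model

A study is a table of enclosure sampling events (`SampleRecord`): tree,
integer day since arrival (day 0 = arrival), replicate index, enclosed bark
area (dm²), sampling duration (h), pump flow (mL min⁻¹), location, and a
background flag. Three phases partition the day axis — acclimation (days
0–8), abiotic stress (9–19) and biotic stress (20–188) by default — and
phase assignment is total on the study window: a day outside every phase is
an error, not a silent drop. Consecutive same-day duplicates are separate
samples for all grouped statistics and are averaged only for the daily
dynamics series.

A compound that was not detected in a sample is a **missing row**, never an
area of zero. Detection frequencies (DF) are therefore counts of present
rows over samples in scope, and the generator's censoring step simply omits
rows. This single convention drives the whole filter cascade and the
symbolic ratio marks; zero-filling would silently change every DF and every
rank test.

## Annotation

The linear retention index is piecewise-linear interpolation of retention
time onto the 100·n grid of the co-analyzed n-alkane ladder (nC₅–nC₁₇).
Outside the ladder span the default is an error; an opt-in flag
extrapolates the terminal segment (real blends contain compounds eluting
before nC₅, reported as index < 500). Library matching ranks candidates by
|ΔLRI| with ties broken lexicographically by name, so output order is
deterministic. The default matching tolerance of 15 index units is our
choice, not a literature constant: observed |LRI_exp − LRI_lit| deviations
for well-identified compounds run up to ~12 units on apolar columns, so 15
accepts those while keeping the 20-unit grid of plausible neighbors apart.
Spectral match scores, when present, are carried through but never
override the index filter — spectral matching happens upstream in vendor
deconvolution software and is out of scope here.

## Quantification

Calibration lines are ordinary least squares **with a free intercept**: the
intercept absorbs the adsorbent blank of spiked thermal-desorption tubes,
and forcing the line through the origin would bias low-level back-
calculations. Back-calculated masses below zero are floored at 0 ng and
flagged `below_calibration` rather than rejected; detections below the
lowest calibration level are expected in trace work. Compounds without a
standard either borrow a structurally related surrogate's curve (tagged
`tentative`) or stay in component-area units (×10⁶ counts dm⁻² h⁻¹);
a table mixing the two unit kinds is an error in the report stage, because
contribution percentages across units are meaningless.

Emission rates are amount/(bark area × duration), homogeneous of degree 1
in amount and −1 in each geometry factor. Background (ambient air) samples
have no enclosed area and cannot be normalized; asking for it is an error.
The background filter retains a feature iff its median trunk area exceeds
`background_factor` (default 2) times its median background area, with
background-absent features always retained. The factor is our choice —
the procedure (background subtraction by location) is standard, the
criterion is not published — and it is configurable.

## Classification rules

Priority: constitutive → stress-induced → herbivore-induced (HIPV) →
neighbor-induced → unclassified. All thresholds compare inclusively
(≥ 10%, ≥ 50%, ≥ 20%, ≥ 2-fold).

* **Retention:** pooled DF ≥ 10% over all trunk samples of all trees.
* **Constitutive:** DF ≥ 50% in *every* tree over the pre-biotic-stress
  phases (1–2). A pooled variant (single DF over all trees' phase-1–2
  samples) is available by config; per-tree is the default because the
  rule is about compounds *all* trees emit continuously, and pooling would
  let one strongly emitting tree carry the others.
* **Means and ratios:** a (tree, period) mean enters a ratio only when the
  compound reached DF ≥ 20% in that scope; sparser scopes are undefined
  and yield symbolic marks: "ALB" for an intra-tree post/pre ratio whose
  pre-scope is undefined (de novo appearance), the emitting tree's name
  when the compound was never detected at either comparison tree, ">"
  when the comparison scope is merely sparse. Symbolic marks count as
  satisfying the two-fold requirement — the denominator was essentially
  absent.
* **De novo** is operationalized as DF < 20% before exposure and ≥ 20%
  after, mirroring the mean-inclusion threshold.
* **HIPV:** de novo at the infested tree, or intra-tree post/pre ≥ 2 and
  ≥ 2 versus both non-infested trees (phase-3 means). Neighbor-induced is
  the mirror image with the neighbor tree as numerator.
* **Stress-induced:** both stressed trees' post/pre ratios satisfied, and
  comparable. "Comparable extent" has no published operationalization; we
  use a factor-2 band (0.5 ≤ r_I/r_N ≤ 2) when both ratios are numeric,
  and treat two de-novo appearances as comparable. A numeric/symbolic mix
  is *not* comparable and falls through to the one-tree rules — a
  compound quantifiable in one tree but barely detectable in the other is
  not "comparably increased in both".
* A compound in the constitutive core that additionally satisfies an
  induced rule keeps **constitutive** as its primary label and carries the
  induced rule as a secondary flag, so primary labels always partition the
  retained set (constitutive volatiles upregulated by herbivory are a
  documented phenomenon, and deserve both annotations).

DF tiers at 50%/30% used in report tables are presentation groupings, not
classification inputs.

## Dynamics

Daily aggregation: mean over the k replicates of a day; SEM = sd/√k
(undefined for k = 1; for duplicates this is |a−b|/2).

The 'Extreme' peak function y = y₀ + A·exp(−e^(−z) − z + 1), z = (x−x_c)/w,
is an asymmetric (Gumbel-kernel) peak with its maximum y₀ + A exactly at
x_c; w > 0 is enforced. Fitting is nonlinear least squares (lmfit,
Levenberg–Marquardt) initialized at x_c = day of the series maximum,
y₀ = min, A = max − min, and w = half the count of days above
half-maximum, floored at one day — a heuristic that is robust for
single-peak shapes; on non-convergence three jittered restarts run from a
fixed seed and the best sum of squares wins. Adjusted
R² = 1 − (1−R²)(n−1)/(n−p−1) with p = 4. Series with fewer than 5 points
or zero variance are rejected rather than fitted. Multi-peak traces are
deliberately fitted with the same single-peak model the field uses for
them — the fit quality column, not a model switch, tells the reader which
series are single-peaked. The pipeline fits *all* induced series and
reports convergence flags instead of silently selecting compounds.

Kendall's τ uses the tie-corrected τ-b variant because censored days and
duplicate-day averaging create ties; correlations are computed on the
intersection of each pair's detected days (dropping, not zero-filling,
undetected days — zero-filling would manufacture concordance from shared
censoring). Grouping is single linkage on the graph of pairs with
τ ≥ 0.5 and p < 0.05, computed within each compound class; ungrouped
compounds stay singletons. The τ threshold sits between reported in-group
ranges (≈ 0.58–0.85) and out-group values (< 0.30).

Kruskal–Wallis is the tie-corrected H with a χ²(k−1) reference; an
all-identical input returns H = 0, p = 1. Note the χ² reference is
conservative for very small groups (n ≈ 3); the test suite checks the
statistic against an exact permutation oracle and the test size at n = 20.
Dunn's post-hoc z statistics on mean ranks use the pooled-tie correction
Σ(t³−t)/(12(N−1)); p-values are two-sided normal, unadjusted by default
(the procedure is used as a labelled descriptive screen), with Holm
adjustment behind a flag.

## Synthetic data generator

The generator emulates the three-tree quarantine design: 42 sampling days
(7 in phase 1, 4 in phase 2, 31 in phase 3 — denser early, drawn without
replacement per seed), duplicates per day, control tree truncated at day
138, ~2 dm² enclosures sampled 1.5 h at 30 mL min⁻¹, and background
samples per location with quarantine backgrounds only from phase 2 on.

Planted mean emission of compound c at tree t, day d:

    baseline_t · stress_multiplier(t, d) + Σ_k kernel_k(d)

with stress multipliers active for trees inside quarantine (phases 2–3)
and induction kernels that are 'Extreme' peaks; sums of kernels produce
double/triple peaks. Observations multiply the mean by unit-mean lognormal
noise (CV 0.2 by default), independently per replicate, and are censored
below a detection threshold (0.1 rate units). Retention times are
back-computed from each compound's true index through the ladder, and
areas back-computed through the calibration line the pipeline will use, so
quantification round-trips exactly. The default panel plants 30
constitutive (aldehyde-dominated, with relocation-sensitive
monoterpenoids), 15 herbivore-induced (an early monoterpenoid wave around
days 30–35, a late broad sesquiterpenoid wave around days 70–75, two
infested-tree-exclusive nitriles in area units; 5 de novo), 6
neighbor-induced (delayed sesquiterpene peaks; 3 de novo) and 4
stress-induced compounds with matched kernels in both stressed trees.

Construction constraint: induction kernels are placed so the rising flank
stays out of the pre-exposure window (x_c − 2.5w past the phase-3 onset)
— otherwise the planted label and the planted dynamics contradict each
other — and de-novo kernels are wide/tall enough that the emitting tree's
post-exposure DF matches the 40–90% range real induced compounds show,
keeping pooled DF clearly above the 10% retention cliff.

What the generator does **not** emulate: co-elution and deconvolution
errors, retention drift between runs, diurnal and weather covariates,
inter-compound correlation of noise, calibration nonlinearity, adsorbent
breakthrough, and single-tree pseudoreplication (each tree is one
biological unit in the real design too). Passing tests on synthetic data
therefore demonstrate the *pipeline's* correctness and the rules'
identifiability under realistic noise — not field-level robustness of the
biological conclusions.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed; a fixed (config, seed)
pair reproduces every output file byte for byte, and the run manifest
records a config hash plus all filter-cascade counts so they can be
audited against brute-force recounts. The shipped experiment sizes — 55
planted compounds, ~250 samples, 200 Monte-Carlo fit-recovery replicates,
5000 Kruskal–Wallis calibration simulations, 10⁵-permutation oracle,
500–1000 random oracle instances — were chosen to make the checks
statistically meaningful at desk scale.
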