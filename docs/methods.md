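# Methods

This note documents the models, conventions and design choices behind
taphomark: what each stage assumes, which knobs matter, what the synthetic
generator does and does not emulate, and the numerical decisions that a
maintainer would otherwise have to reverse-engineer from the code.

## Cross-section model and segmentation

A transect is a 1-D height profile z(x) in micrometers crossing a single
groove. The unmodified bone surface is modeled, within the transect, as a
straight line (the cross-section of a plane). All depths and heights are
residuals from that line.

**Reference-line estimation.** `fit_reference_surface` is an ordinary
least-squares line through the samples outside a caller-supplied exclusion
interval. When no interval is given, `auto_exclusion` finds one: a trimmed
iterative fit (keep the 75%, then 60%, then 50% of samples with smallest
absolute residuals, then a final 2.5-sigma MAD band) peels the groove and any
raised rim off as outliers; the exclusion interval is then the contiguous
residual disturbance around the deepest point, bridging calm gaps shorter
than n/32 samples (wall zero-crossings), padded by 5% of the span. This
assumes the groove plus rim occupy a minority of the transect — profiles
should be scanned with generous unmodified surface on both flanks. A groove
spanning most of the window will capture the reference line and the stage
reports "no groove found".

**Segmentation.** The base is the global minimum of the detrended profile and
must lie below the reference by more than twice the reference-fit residual
sd; otherwise `NoGrooveError` is raised (flat or monotone profiles). Each
shoulder is, walking outward from the base: the nearest local maximum that
rises clearly above the reference (a raised rim), or, when no such maximum
exists, the interpolated point where the wall crosses the reference line. A
candidate rim must exceed max(4 × residual sd, 3% of depth) — smaller rims
are not distinguishable from noise, and treating a sub-noise bump as the
shoulder would silently collapse the wall-asymmetry measure to its crossing
value. Always preferring the *lower* of {local maximum, crossing} was
considered and rejected: with any genuine raised rim the crossing is always
lower, which forces measure 3 = 1 by construction and destroys the quantity
the measure exists for. Under noise, the first upward crossing is biased
toward the base (noise triggers it early on the wall); the crossing is
therefore refined by fitting a line to the wall samples just inside and
projecting it to the reference level. On noiseless input the refinement is
skipped and the interpolated crossing is exact. If a second depression
deeper than max(2 × residual sd, 25% of the groove depth) exists outside the
segmented groove, the deeper groove is kept and a warning is emitted.

**Measures.** Breadth B is the horizontal distance between shoulder points;
depth D the drop from the reference line to the base; B25 the interpolated
width of the groove at base + 0.25 D (linear interpolation between bracketing
samples, resolution-independent); wall heights are measured from the base to
each shoulder, higher ÷ lower giving measure 3 ≥ 1 by construction.
Measure 4 fits a least-squares line to each wall over the samples whose
height lies in the 25%–75% band of the depth (excluding the curved base and
shoulder rounding; the band is a parameter), intersects the two lines, and
reports apex depth ÷ D: exactly 1 for an ideal V, 1/0.8 = 1.25 for a V
truncated at 80% of its apex depth, larger for blunter bases. The wall-fit
residual sd is reported as a straightness diagnostic, and an apex deeper
than 10 × D is flagged unstable (near-parallel walls). The geometric-mean
normalization of measure 1a divides the ratio B/D by GM(B, D, h_hi, h_lo);
the raw ratio is retained alongside. Mark-level measures 5–7 are sample
CVs (divisor k − 1) of measures 2–4 over the k ≥ 2 transects of a mark;
`max_dimension` is the maximum transect breadth — a documented proxy, since
full planform length is not recoverable from three transects.

## Synthetic grooves

The generator cuts a parametric groove into a flat surface at z = 0 and adds
i.i.d. Gaussian height noise. The wall shape is the superellipse arc
z(t) = −D + h·g(t), g(t) = 1 − (1 − t^e)^(1/e), t ∈ [0, 1] from base to
shoulder, with exponent e = 1 + curvature for the V form (e = 1: straight
walls, exactly piecewise-linear profiles) and e = 2 + curvature for the U
form (e = 2: circular arc). Shoulder asymmetry a ≥ 1 raises one rim to
(a − 1)·D above the reference, decaying linearly back to the surface over a
quarter-breadth, so the wall heights above the base are a·D and D and the
true measure 3 equals a. The sample grid spans ±1.5 breadths with the
geometry breakpoints placed on exact sample positions, which makes the
noiseless closed forms attainable to interpolation accuracy (≲ 1e-6 relative
at 8192 samples — the oracle tests' density; the default 256 is plenty for
noisy work at realistic noise).

Ground truth: B, D, the wall heights, B25 and measures 1–3 are closed forms
of the superellipse. Measure 4 of a curved wall is the intersection of two
least-squares fits and has no convenient closed form; its ground-truth value
is defined as the measurement of a dense noiseless realization of the same
parameters, and is cross-checked in tests against an independently coded
fit-and-intersect route. A consequence worth knowing: for e = 1 the true
measure 4 is exactly 1 regardless of asymmetry, because both straight walls
pass through the base.

Longitudinal variability: `simulate_mark` draws each transect's breadth,
depth, asymmetry excess and curvature as the mark-level value times
independent lognormal factors with log-sd equal to the jitter parameter.
True measures 5–7 are the CVs of the true per-transect measures, so zero
jitter gives exactly zero CVs.

**Populations.** log(B × D) is Gaussian; defaults place the aquatic group at
log-mean 8.0 (≈ 3 000 µm², breadths near 90 µm) and the terrestrial group at
10.1 (≈ 24 000 µm²), both with log-sd 0.7 — chosen so the groups differ by
roughly 3 sigma, a separation a rank test detects essentially always at
n = 30 + 30, which is the qualitative regime the analyses assume (clearly
smaller aquatic marks). Aquatic marks are more often U-sectioned (probability
0.5 vs 0.15) with breadth:depth ratio centered at 2.5 vs 2.0. The coupling of
size to longitudinal variability is linear in centered log size:
jitter = clip(0.15 + slope·(log s − µ), 0.02, 0.6) with slope ≤ 0 (default
−0.08), so smaller marks are more variable along their length; slope 0 is
the calibrated null. No distributional information beyond the direction of
these contrasts is available from published summaries, so the defaults are
calibration choices, recorded here once.

## Synthetic blind test

Defaults mirror the reference protocol: 9 participants (5 hand-lens, 4
microscope; 4 sharing teaching tradition TT1 giving 6 within-group pairs,
the other 5 forming TT2 with 10 pairs), 36 specimens — 5 with intrinsic
features only ("none") and 31 modified, spread 8/8/8/7 over cut/scrape,
percussion, human-tooth and trampling — and one participant who skips 4
specimens (which instrument group that analyst belonged to is not published;
the generator assigns the skip to a microscope user, and the scoring
denominators make the choice immaterial to the implemented comparisons).

Presence calls on modified specimens are Bernoulli with probability given by
an instrument-specific logistic curve in log max dimension, non-decreasing in
size, the microscope curve dominating the hand-lens curve (midpoints 50 µm vs
70 µm, floors 0.40 vs 0.25, ceilings 0.99 vs 0.95); intrinsic-only specimens
draw false positives at instrument-specific rates (0.20 / 0.30). Diagnoses
of detected marks come from a per-category confusion matrix whose default
encodes the field's known failure mode: trampling abrasion and cut marks
confuse each other (row-probability 0.25–0.30 of crossing), other categories
are mostly faithful. Confidence (1–5) is generated as
1 + 4·(1 − H(row)/H_max) plus rounding noise, where H is the confusion-row
entropy of the true category — so categories that are objectively harder get
lower confidence, which is what makes a positive confidence–success
correlation reproducible rather than accidental.

What the generator does **not** emulate: per-analyst skill heterogeneity
beyond the instrument split, specimen-level difficulty beyond size, learning
or fatigue over the test, and any dependence between specimens. Passing
calibration tests therefore demonstrates that the scoring and statistics
recover designed-in effects at realistic sizes, not that real analysts
behave this way.

## Scoring conventions

Locating success counts a presence call matching the key ("none" specimens
require an absent call); diagnosing success counts category-exact calls, with
a correct "absent" on an intrinsic-only specimen counting as a correct
diagnosis (trap items). Two-way correspondence divides by the specimens
answered by *both* analysts of a pair — only jointly scored specimens can
agree — and group comparisons use within-group pairs only. Published summary
tables store integer percentages and the reference analyses demonstrably ran
on them, so table-driven comparisons round to integers by default
(`round_percent`); full-precision values are always computed alongside.

## Statistics kernel conventions

The printed small-sample results are reproducible only under one specific
convention set, which is therefore the default and is exposed flag by flag:

* Mann-Whitney: midrank ties; reported U = min(U₁, U₂); tie-corrected normal
  variance σ² = (n₁n₂/12)·[(N+1) − Σ(t³−t)/(N(N−1))]; continuity correction
  0.5 toward the mean; z signed from the first sample's rank sum.
* Wilcoxon signed-rank: zero differences dropped before ranking (reducing n);
  midranks on |d|; W = sum of positive-difference ranks; tie-corrected
  variance n(n+1)(2n+1)/24 − Σ(t³−t)/48; **no** continuity correction.

Exact-enumeration oracles (all C(N, n₁) labelings; all 2ⁿ sign assignments)
bound the normal approximation in the tests. One caveat discovered while
validating: without continuity correction the Wilcoxon normal p can differ
from the exact two-sided p by up to 0.050 at n = 10 (exhaustively checked
over all W), while the corrected variant stays within 0.017; the enumeration
oracle therefore exercises the corrected path, and the uncorrected default
is validated against the printed z values it exists to reproduce.

Kendall's tau-b, Shapiro-Wilk and one-way ANOVA delegate to scipy; Tukey HSD
computes Q = |ȳᵢ − ȳⱼ| / √(MSW/2·(1/nᵢ + 1/nⱼ)) with a studentized-range
tail (cross-checked against scipy's implementation in tests). PCA is an
explicit eigendecomposition of the correlation matrix (the measures are on
incommensurate scales; covariance PCA is available via a flag), with each
component signed so its largest-magnitude loading is positive. Degenerate
inputs (zero rank-test variance, constant columns, all-zero differences) are
flagged as degenerate results or rejected by name rather than returning NaN
silently.

## Micro-hardness

Hv = F/D², D the mean of the two indent diagonals — deliberately the
simplified field formula, kept as the default for fidelity with the hardness
values the rest of the pipeline is calibrated against; the conventional
1.8544·F/D² (indenter geometry factor) is the "standard" variant. The two
differ by a constant, so between-class comparisons are identical under
either. Diagonals differing by more than 50% of their mean are flagged, not
rejected. Specimen-level hardness is the mean over that specimen's indents
(with within-specimen CV reported); the class battery reports a Shapiro-Wilk
normality gate on the pooled values, one-way ANOVA with Tukey HSD, and
pairwise Mann-Whitney tests alongside — the parametric and nonparametric
routes are both printed because hardness across bone classes is typically
non-normal. Synthetic indentations are generated hardness-first: Hv is
sampled per class (defaults: catfish 48, reptile 38, cancellous 30, cortical
36 kgf·mm⁻², sds 6–8, class sizes 45/10/13/39 — aquatic harder, in the
simplified-formula scale) and the diagonals back-computed so the round trip
is exact to machine precision; the diagonal split d₁,₂ = D(1 ± δ), δ ≤ 0.05,
preserves the mean exactly.

## Pipeline, sizes, run times

The CLI stages (simulate → measure → score → hardness → stats → report) pass
flat CSVs with a manifest (config hash, seed, version). Profile CSVs are
written with %.17g and read with round-trip float parsing, so numeric fields
survive a write/read cycle bit-exactly. The `report` stage is pure: it
recomputes the reference-table statistics from the packaged, checksummed
fixture transcriptions and touches nothing else.

Default problem sizes — 40 marks per group at 3 transects of 256 samples,
a 9 × 36 blind test, 107 indentations — run the full pipeline in a few
seconds; the Monte-Carlo calibration tests use 100–200 replicates on the
generator's profile-free fast path (closed-form truth tables only), keeping
the whole suite under a minute on one CPU. The acceptance script uses 31
marks per group, matching the 62-mark measured assemblage of the reference
study.

## Known limitations

* Transect-only: no full-3D surface segmentation or mesh handling; planform
  quantities (true mark length) are proxied by maximum transect breadth.
* The reference-line model is linear per transect; strongly curved bone
  surfaces need detrending upstream.
* Segmentation assumes one dominant groove mostly narrower than the scan
  window; overlapping grooves of similar depth are resolved arbitrarily
  (deeper wins, with a warning).
* Rims smaller than max(4 × noise sd, 3% of depth) merge into the reference
  surface, so very subtle shoulder asymmetry is reported as 1 under noise.
* The blind-test generator's analysts are exchangeable within instrument
  group; it cannot produce analyst-level fixed effects, and the GLMM-style
  joint analysis of influences is out of scope.
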