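# Methods

This note documents the models and procedures `retinagaze` implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices a maintainer would want written down.

## Display geometry and remapping

The viewer shows the image in a 1140×848 px region of a 1920×1080 monitor,
bordered by 390 px left/right, 222 px above and 10 px below (the screen
area where this tracker/monitor pairing is most accurate; the layout
invariant `borders + region = screen` is enforced). Gaze is stored as a
fraction of the display region, which makes logs layout-independent; a
converter from absolute screen pixels is provided.

Zoom levels form the geometric ladder 1.5^k (each zoom-in step magnifies
by 150%): 1.0, 1.5, 2.25, 3.375 (printed as 3.38), 5.06, … The viewport —
the visible sub-rectangle of the original image — is carried on every
sample; remapping is `origin + fraction × size`, exact and real-valued
(rounding only happens at mask lookups). Coordinates are 0-based, x
rightward, y downward.

**Zoom-transition invalidation.** Saccades to re-foveate after a zoom
change have a latency of roughly 200 ms, so samples in
`[t_change, t_change + 200 ms]` are invalidated. The window is one-sided
by default because the latency argument concerns gaze *after* the change;
whether it should also cover pre-change samples is genuinely open, so a
`two_sided` flag provides the alternative. The closed/closed boundary
convention is asserted in tests.

**Tracker accuracy.** The accuracy of this tracker in the display region
is 1.59°. By the tangent formula (`distance × tan θ / pitch`: 600 mm,
0.2744 mm/px) that is ≈61 px, yet the radius used operationally for
annotation expansion is 70 px. The package keeps both deliberately:
`TrackerAccuracy.expansion_radius_px` defaults to 70 and
`degrees_to_pixels` exposes the plain conversion; the discrepancy is the
upstream convention, not an implementation bug. The radius is fixed across
zoom levels — it is therefore conservative (overestimated) when zoomed in.

**Fixation detection.** The study hardware reports fixations; for
synthetic raw logs an I-DT detector is provided: maximal windows of
consecutive valid samples whose bounding-box extent (width + height) stays
within the dispersion threshold and that span the minimum duration become
fixations at the window centroid. Defaults: dispersion 70 px (the
accuracy radius), minimum duration 100 ms. Invalid samples break windows.
The final sample of a window contributes the median inter-sample interval
to the duration, so an n-sample stationary burst at rate r lasts n/r.

## Areas of interest

Alphabet: D (optic disc), M (macula), S/I (superior/inferior temporal
arcade), plus B (background) for fixations matching nothing; B never
appears in exported pattern strings. The macula is a 5.5 mm-diameter
circle centred on the foveola, with the image's mm scale recovered from
the 4.76 mm disc–fovea distance. Annotation masks are dilated by the
expansion radius using the exact Euclidean distance transform (the
expanded mask is precisely the set of pixels within the radius of an
annotated pixel — verified against a brute-force distance scan). Expanded
masks may overlap; overlap is resolved at the string stage. Fixation
membership uses the rounded centroid, not an area test.

**HMM-derived AOIs.** Gaze positions (temporally ordered) are clustered
with a Gaussian-emission hidden Markov model: full covariance, k-means
initialisation, 5 restarts per candidate state count, up to 500 EM
iterations at tolerance 1e-4, all seeded. The state count is selected by
BIC over k ∈ {2…6} by default; assignment is Viterbi decoding. The EM
log-likelihood history is recorded in full (a custom convergence monitor)
so monotonicity is assertable per iteration. Degenerate input (all points
identical) returns a single-state model with a warning. A fitted model is
mapped to anatomy by locating each state mean in the expanded annotation;
a response "covers all four landmarks" when every anatomical label claims
at least one state. HMMs are fitted per response; pooling across responses
is the caller's choice (pass concatenated points).

## Fixation strings

Candidates per fixation form a layer of a DAG; edges between adjacent
layers cost 1 across different labels, 0 across equal labels, with a
zero-cost virtual source and sink. The minimum-cost source-to-sink path —
the assignment with the fewest AOI transitions — is computed by a
backward dynamic program plus a forward walk; exactness is enforced by an
exhaustive-enumeration oracle on instances up to 10 layers × 3 candidates.
Ties are broken deterministically: continue the previous fixation's label
when that stays optimal, else the fixed priority M > D > S > I > B
(continuity first, macula-centrality second); the tie-break is a policy
choice, not part of the optimality contract.

Background fixations are ordinary vertices (entering/leaving B costs 1
like any change) and are removed from the exported pattern afterwards. Two
collapsing policies exist because the interaction of B with run merging is
underdetermined: the default merges across B (M,B,M → "M"); the strict
mode (`b_breaks_runs=True`) lets B terminate a visit, which matters for
visit counts and dwell times, while the exported pattern is re-collapsed
either way so it never carries adjacent duplicates. Patterns therefore
satisfy: no B, no two adjacent equal symbols, and the transition count of
the resolved sequence equals the reported cost.

## Grading metrics and statistics

Severity grades: 0 none, 1 mild NPDR, 2 moderate NPDR, 3 severe NPDR,
4 proliferative DR, or ungradable. The grade score is `grade − reference`.
Criteria: EXACT (score 0); LENIENT (scores {0, +1} — over-grading by one
level triggers at most an unnecessary referral, under-grading delays care,
so only +1 is tolerated); REFERABLE (agreement on the referable boundary,
level ≥ 2). Ungradable responses are incorrect under every criterion.
EXACT-correct ⊆ LENIENT-correct on any dataset.

Per-AOI metrics per response: fixation count, visits (maximal runs in the
resolved sequence), total time (summed fixation durations), dwell times
(one per visit). B breaks a visit by default (`merge_across_background`
reverses this); B durations are never credited. Conservation (Σ dwell =
total per label) is asserted. Zoom-time fractions weight each valid sample
by the interval to the next valid sample (final sample: median interval);
a `max_gap_ms` cap is available when invalidation gaps should not be
credited to the pre-gap level.

Group comparisons use the two-sided Mann–Whitney U (scipy; exact for small
tie-free samples, tie-corrected normal approximation otherwise), reporting
U of the first sample so `U_a + U_b = n_a n_b`. Dwell-time comparisons
pool individual visit durations across responses; count/visit/total-time
comparisons pool per-response-per-AOI values — the former unit gives the
much larger n that dwell-time tests need. No multiple-testing correction
is applied by default.

Krippendorff's alpha is computed from the coincidence matrix with
pairable-value weighting for missing entries. The ordinal distance is the
squared cumulative-margin form `δ_ck = (Σ_{g=c..k} n_g − (n_c+n_k)/2)²`;
ordinal is used for the 5-level scale and nominal for referable /
not-referable. Hand-computed fixtures (nominal two-rater example → 8/15;
ordinal three-unit example → 1/6) pin the implementation.

## Search-pattern clustering

Distances are unit-cost Levenshtein on the run-collapsed pattern strings
(compact strings are what the exemplars should read as). Affinity
Propagation runs on the negative distance matrix with damping 0.9,
max_iter 1000, convergence_iter 50, and the median similarity as the
preference (AUTO) — these hyperparameters are this package's choices.
Duplicated inputs routinely produce several textually identical exemplars;
clusters sharing an exemplar string are merged so each pattern is reported
once with its total support (the partition property is preserved).
Non-convergence falls back to a single medoid cluster with a warning flag.
Top clusters are the size-sorted prefix (ties broken lexicographically)
covering the requested share of responses, default 75%. The
correct-vs-incorrect length comparison is run on exemplar pattern lengths
(the cluster-level unit implied by the small U statistic of the original
comparison), skipped when either group has fewer than two clusters.

## Synthetic cohort generator

Defaults are the study conditions: 23 graders (15 optometrists, 8
ophthalmologists) × 20 images, four per severity grade; 150 Hz sampling;
the 1.5^k zoom ladder; image/display region 1140×848.

**Layouts.** A schematic posterior pole (synthetic stand-in for annotated
fundus photographs): scale 76 px/mm (a ~15 mm field across the region),
disc placed nasally with small seeded jitter, foveola 4.76 mm temporal,
macula per the 5.5 mm circle, arcades as 3 px-wide vessel arcs sweeping
from the disc margin around the macula at a radius that clears the
expanded macula — raw masks are disjoint and every label keeps an
unambiguous "core" after expansion, while the expanded masks overlap the
way real annotations do. Real vessels bifurcate; these arcs do not, so the
thicker-branch annotation rule for real arcades is out of scope.

**Responses.** Structured responses walk a canonical sequence (default
"MSID") with 2–4 fixations per AOI; bases are sampled from the AOI's core
pixels (a deliberate look aims at the landmark) with 20 px Gaussian
scatter; durations are lognormal (median ≈0.27 s, σ_log 0.35). Saliency
responses fixate 8 random points ordered nasal→temporal — a minimal
stand-in for stimulus-driven search, not a quantitative saliency model.
Saccades are linearly interpolated over ~30 ms and are rejected by the
I-DT dispersion criterion; blink bursts (~100 ms, p = 0.05 per saccade)
are flagged invalid. Zoom events (Poisson, mean 3 per response) jump to a
level drawn from weights {1.0: 0.34, 1.5: 0.26, 2.25: 0.05, 3.375: 0.33,
5.06: 0.02}, recentre the viewport on the current target (clamped), and
are followed by 250 ms of settling samples that downstream invalidation
removes; panning while zoomed recentres without a zoom change. Because
every response starts at native zoom, the realised time fraction at 1.0×
runs somewhat above its configured weight. Tracker jitter is 6 px in
screen space, so image-space jitter shrinks when zoomed in.

**Grades.** Confusion is offset-based around the reference: P(0) = 0.648,
P(+1) = 0.161 (so exact and lenient agreement are 0.648 and 0.809),
P(−1) = 0.120, P(−2) = 0.034, P(+2) = 0.030, P(ungradable) = 0.007.
Offsets that would leave the 0–4 scale are *reflected* (sign flipped)
rather than clipped or resampled: reflection preserves P(score = 0) at
every reference grade, so cohort exact accuracy matches P(0); clipping or
renormalisation would inflate it at the scale ends. Correct responses
follow the structured strategy with probability 0.85, incorrect ones with
probability 0.35. Decision times are a single lognormal draw, present only
to complete the response table — they are not modelled.

**What passing tests do not show.** The generator produces clean
stationary fixations, ideal viewport bookkeeping, stylised anatomy and an
exchangeable confusion model (no image- or grader-specific difficulty,
no learning effects). Recovery results on it validate the pipeline's
internal consistency — remapping, cleaning, detection, labelling,
resolution and clustering compose correctly — not clinical conclusions
about real graders.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` (PCG64) seeds;
identical config + seed reproduces byte-identical tables. Test and
acceptance runs use scaled cohorts (3–6 graders × 4–8 images for
end-to-end checks; 20-seed batches of 30 structured responses for pattern
recovery; 300-point planted mixtures for HMM selection), chosen as the
smallest sizes at which the checked properties are stable across seeds.
The full 23×20 cohort runs in well under a minute on one core.

## Known limitations

- The DAG resolver optimises transition count only; edges weighted by
  saccade length or fixation duration are out of scope.
- The accuracy radius is fixed across zoom levels (conservative when
  zoomed in).
- Affinity Propagation with median preference can over-fragment small
  groups; exemplar merging mitigates but damping/preference may need
  tuning for very heterogeneous string sets.
- Krippendorff's alpha is reported without a bootstrap; comparing alphas
  between image groups therefore has no significance test here.
- Diabetic macular oedema grading is not evaluated anywhere in the
  package.
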