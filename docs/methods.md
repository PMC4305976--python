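# Methods

## The statistic and the estimation problem

The quantity of interest is the positivity percentage (labelling index)
of an immunohistochemistry image:

    p = 100 · N_pos / (N_pos + N_neg)

where `N_pos` and `N_neg` are the counts of positive (stained) and
negative (unstained) tumour nuclei. Stromal cells and lymphocytes — the
"other" class — are present in the tissue but excluded from the
statistic by definition. The reference truth is a pathologist's
per-nucleus point annotation; the crowd estimate is built from
contributors' click lists, which carry only positive/negative labels
because the counting interface offers no "other" button.

Coordinates are 0-based pixels with the origin at the top-left and y
increasing downward (web-canvas convention); the reference geometry is
the rotated-vertical image, 772 × 1044 px. Percentages are carried on
the 0–100 scale everywhere; fractions appear only inside formulas.
A zero denominator raises an explicit undefined-statistic error — the
pipeline never silently reports 0 or NaN for an empty count.

## Worker error model

A simulated contributor is parameterised by:

| parameter | meaning | default |
|---|---|---|
| `s_pos`, `s_neg` | detection probability per positive / negative nucleus | 0.9 |
| `s_other` | probability an "other" nucleus is wrongly clicked (always labelled negative) | 0.2 |
| `confusion` | probability a detected nucleus gets the flipped label | 0.02 |
| `fp_rate` | expected spurious background clicks per image (Poisson, uniform on canvas) | 2 |
| `fp_neg_share` | probability a spurious click is labelled negative | 0.7 |
| `jitter_sd` | isotropic Gaussian click displacement, px | 3 |

This is the minimal family producing the three error phenomena that
matter for the statistic: detection misses, wrong-class counting, and
spurious clicks. Richer structure (spatial attention decay, fatigue,
worker learning) is deliberately excluded. The closed-form expectation

    E[p̂] ≈ 100 · s_pos·N_pos / (s_pos·N_pos + s_neg·N_neg + s_other·N_other)

shows the two structural biases the model encodes: equal thinning
(`s_pos = s_neg`, `s_other = 0`) is neutral in expectation, while any
`s_other > 0` strictly depresses the estimate below gold — the
direction of the negative-nucleus overcount observed in real crowd
data. Both properties are verified by Monte-Carlo tests (n = 2000
judgments, 3-standard-error bands).

Numerical details: jitter is clamped to the canvas rather than
resampled, preserving click counts (which drive the statistic); clicks
are rounded to integer pixels (screen clicks are integral), and a
pixel collision between clicks with conflicting labels is resolved by
a deterministic 1-px nudge. `fp_neg_share = 0.7` reflects that most
background is unstained material; it is a free choice with no
published value behind it.

## Synthetic fields and the collection design

Gold fields are generated by random sequential packing of integer
pixel centres with a hard-core minimum separation (default 24 px,
chosen so ~150 nuclei fit comfortably on the canvas while click
clusters remain separable at the 15 px consensus radius; packing
failure after 500 placement attempts per nucleus raises an error
naming the constraint). The study-sized panel
(`make_study_fields`) uses 13 images whose gold positivities spread
evenly over 2–80%, each with 120 countable nuclei plus 30 "other"
nuclei — a realistic stromal admixture for a 40× field.

The collection design mirrors the crowd experiment the pipeline
analyses: 10 judgments per image, workers taking up to 13 units, never
the same image twice. Worker-to-image assignment is round-robin over a
seeded shuffle of the pool; infeasible demands (pool smaller than the
per-image quorum, or total capacity below the judgment count) raise
capacity errors up front. With a 28-worker pool this yields 130
judgments at 130/28 ≈ 4.64 units per contributor. Simulated
behavioural metadata (elapsed time log-normal around 163 s,
end-attempts and afterthoughts small Poisson counts, countries cycled
through an 18-country pool) are descriptive plumbing only; no analysis
depends on them.

All randomness flows through seeded `numpy` generators; identical
seeds give byte-identical outputs, including the written files.

## Quality gates

Two per-judgment controls: at least `min_total_cells` clicks (default
20), and at least one click with y in the bottom `lower_fraction` of
the canvas (default 0.5) — evidence that the contributor scrolled the
vertical image to its end. Both comparisons are boundary-inclusive (a
stated minimum admits equality). The real experiment's thresholds were
not published; the defaults are documented assumptions, and both are
configuration values. Gate-failing judgments are excluded before
aggregation (discarded work), never zero-filled.

## Aggregation

The crowd estimate of an image is the median of its valid judgments'
positivity percentages — per-judgment percentages, not pooled click
counts, so each contributor's count is summarised before the crowd is.
With an even number of judgments (the design collects 10) the median
is the midpoint of the central pair; this convention is load-bearing
and tested. Mean and trimmed mean (default trim 10%) are provided as
alternatives; `numpy`/`scipy` stand behind all three.

## Concordance evaluation

* **Spearman ρ** with average-rank ties, written from first principles
  (rank transform + Pearson on ranks) so a brute-force oracle can
  verify it exactly; the test suite cross-checks it against
  `scipy.stats.spearmanr` on 200 random small instances. On the
  bundled 13-image reference table the printed 2-decimal values give
  Σd² = 22, hence ρ = 1 − 6·22/(13·168) = 0.9396.
* **OLS of crowd on gold** via the closed-form normal equations;
  residuals sum to zero by construction. The fit direction is fixed as
  crowd-on-gold so the intercept reads as the crowd's offset at zero
  true positivity (3.09% on the reference table); the reverse fit can
  be obtained by swapping arguments but is not the default.
* **15% cutoff** classification is boundary-inclusive (p ≥ 15 is
  "above"). A false positive is an image the crowd pushes above the
  cutoff against gold; a false negative the reverse.
* p-values for ρ are reported as "not computed": at n ≈ 13 the
  asymptotic approximation adds nothing, and the rank statistic itself
  is the deliverable.

With fewer than 3 images the correlation is flagged unavailable rather
than fabricated; regression still requires 2 non-degenerate points.

## Spatial click consensus

The pooled-click extension treats a spatial cluster of clicks from
several judgments as one crowd-identified nucleus. Greedy density
clustering: repeatedly seed at the pooled click with the most
neighbours within `cluster_radius` (default 15 px, roughly a nucleus
radius at this magnification; ties broken by lowest y then lowest x,
so the result is invariant to judgment order), absorb at most one
click per judgment (nearest within the radius — a double-click cannot
inflate support), remove, recurse. Support thresholding keeps nuclei
backed by at least `min_support` judgments (default: a majority).
Matching to gold is greedy nearest-pair within `match_radius`, each
side used once; gold "other" nuclei are never match targets, so a
consensus nucleus sitting on one is counted spurious — deliberately
surfacing the stromal-confusion error. Consensus positivity uses
majority labels, ties broken toward negative (conservative with
respect to clinical positivity). Greedy clustering was chosen over
global optimisation because it is deterministic and oracle-checkable
on tiny instances, and adequate at nucleus densities where the
separation exceeds the cluster diameter.

## What the synthetic data does and does not show

The simulator reproduces the statistical structure the analysis
assumes — per-class detection, stromal miscounting, spurious clicks,
jitter, the collection design — and under it the full pipeline
recovers the gold ranking (ρ ≥ 0.9) and the cutoff classification for
all images at least 5 points from the cutoff in ≥ 90% of seeded
replicates. It does not model image appearance, worker skill
correlation across images, fatigue, or adversarial workers; passing
tests therefore validate the pipeline's arithmetic and its robustness
to the modelled error family, not crowd behaviour on real images. The
bundled 13-image reference table is the only real-data surface.

## Problem sizes

Default test and reproduction runs use 13 images × 120 countable
nuclei × 10 judgments, 2000-judgment Monte-Carlo checks, and 50
replicates for the recovery property — sizes at which every
distributional check is stable yet the whole suite runs in well under
a minute.

## Known limitations

* Gate thresholds and the consensus radius are assumptions exposed as
  configuration, not fitted values.
* The simulator's error rates are plausible defaults, not estimates
  fitted to any crowd dataset.
* Consensus clustering degrades when nuclei sit closer than the
  cluster diameter; no splitting heuristic is attempted.
* No inferential statistics (confidence intervals, bootstrap) beyond
  the point estimates.
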