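# Methods

## Similarity measures

A transcript is tokenized by whitespace, with leading/trailing punctuation
stripped, hyphens/slashes treated as separators, and word-internal
apostrophes preserved (`it's` is one token). Tokens are lower-cased before
any lookup (configurable to `preserve`; the default maximizes vocabulary
coverage for spoken-language transcripts, where casing is a transcription
artifact). Stop words are *marked*, not deleted: NW counts every
non-punctuation token, which is what puts a one-minute description near 70
words, while similarity is computed over eligible words only —
in-vocabulary and non-stop (an `include_stops` flag exists for sensitivity
analyses; including them compresses group differences toward stop-word
co-occurrence). Words missing from the embedding table are flagged, logged,
and reported per transcript in `oov_report.csv`; they never enter the
similarity computation and never contribute zeros.

ASW-F is the mean cosine over all unordered pairs of eligible word vectors
in the frame (`pair_mode="all_pairs"`, the default — "mean similarity over
the frame" reads as all-pairs; an `adjacent` mode averaging only successive
pairs is implemented for comparison, and the mode used is recorded in every
output row). ASW-10 slides a 10-token window over the *eligible* sequence
(stop/OOV words are removed before windowing) with step 1, emitting full
windows only; when the sequence is no longer than the window the whole
sequence is the single frame, so ASW-10 equals ASW-F exactly. Sequences
with fewer than two eligible words have undefined similarity, propagated as
missing values — never as 0. Subject-level scores are arithmetic means over
that subject's (typically 3) picture descriptions, with undefined pictures
excluded from the mean and a warning logged.

The stop-list shipped in `semsim/data/stopwords_en.txt` is a conventional
~170-word English function-word list (versioned as `stopwords_en_v1`,
overridable per run). The exact list used by any particular upstream tool is
not recoverable; the list is a free parameter and is recorded in outputs.

## Cognitive scores

Stroop interference uses the Golden formulation: predicted colour-word score
`W·C/(W+C)` from the word-reading and colour-naming counts, interference
`IG = CW − predicted`. The formula is symmetric in W and C, bounded by
`predicted ≤ min(W, C)`, and `W + C = 0` is a domain error. The DSST total
is the mean of the oral and written correct counts. Category-fluency word
lists can be routed through the same tokenize → annotate → ASW path,
treating the one-minute response list as the frame.

## Bayesian battery

All tests are two-sided by default and compare a default-prior alternative
against a point null; priors are parameters, recorded in every result.

* **t-tests.** The JZS Bayes factor with Cauchy width `w = 0.707` on δ is
  computed as a one-dimensional integral over the Zellner–Siow mixing
  parameter `g ~ InvGamma(1/2, w²/2)` of the likelihood ratio implied by the
  t statistic, with adaptive quadrature at 1e-10 absolute/relative
  tolerance; non-convergence raises with diagnostics rather than returning
  silently. Summary-statistic input `(m, sd, n)` per group maps to a
  pooled-variance t by default (Welch with Satterthwaite degrees of freedom
  available); results computed from summaries are flagged `rounded_input`.
  The δ posterior is evaluated on a 4001-point grid of
  Cauchy-prior × noncentral-t likelihood and summarized by the median and
  central 95% interval. The test suite checks the integrator against an
  independent oracle that integrates the noncentral-t likelihood directly
  against the Cauchy prior (no g-mixture), to 1e-6 relative error.
* **Correlation.** Jeffreys-style test from `(r, n)` sufficiency: the exact
  hypergeometric sampling density of r is integrated against a
  stretched-beta prior of width κ = 1 (uniform on (−1, 1)). One-sided
  variants restrict and renormalize the prior to a half-line. Cross-checked
  against the closed hypergeometric form to 1e-6.
* **One-way ANOVA.** Group effects in an orthonormal sum-to-zero basis carry
  a `N(0, g σ² I)` prior with `g ~ InvGamma(1/2, r²/2)`, `r = 0.5`; the
  Bayes factor is a 1-D integral over g of a determinant/residual ratio.
  With two groups this is *exactly* the JZS t-test with Cauchy width
  `√2 · r ≈ 0.707` (verified to machine precision), so the default scales
  are mutually consistent. The reported effect size is the posterior median
  of η² from conjugate draws of the cell means (internally seeded, so
  reruns are deterministic).
* **Contingency.** Gunel–Dickey independent-multinomial Bayes factor with
  per-cell prior concentration a = 1, rows (groups) fixed by design: each
  row has its own Dirichlet(a) vector under H1, all rows share a
  Dirichlet(r·a) vector under H0; closed form in log-gamma functions. Zero
  margins are domain errors. Effect size: posterior median Cramér's V from
  Dirichlet draws.

`BF10` is always the alternative-over-null factor; `BF01` its reciprocal.

## Pipeline conventions

Change scores are computed on subject-level aggregated linguistics
(follow-up minus baseline), standardized change divides by the baseline
value and is set missing (with a warning) when the baseline is 0. Analyses
are complete-case per row, with the n used always reported. No
multiple-testing correction is applied; each row carries its own Bayes
factor. Presentation tables round Bayes factors to 3 significant figures
and moments to 3 decimals; raw-precision CSVs are emitted alongside.
Rerunning on identical inputs produces byte-identical files.

## Synthetic cohort generator

The generator emulates the *statistical* structure the analysis assumes,
not language. Its components:

* **Embedding space.** K = 20 cluster centres in 50 dimensions, all sharing
  a common component so any two words have baseline cosine ≈ 0.30 (GloVe
  cosines over content words are predominantly positive), plus a
  cluster-specific axis; each cluster holds 25 members whose axes are
  perturbed with noise scale 1.35–1.6, putting within-cluster cosine near
  0.50 and between-cluster cosine near the 0.30 floor. Stop-list words get
  unrelated random vectors; 30 designated OOV surfaces exist in the lexicon
  but are withheld from the table.
* **Transcripts.** A description is a Markov cluster walk over content
  positions: the first content word comes from a uniform cluster, each next
  content word stays in the current cluster with probability `p_stay`, else
  jumps to a uniformly chosen different cluster; words are uniform within
  cluster. Stop words are interleaved at rate 0.35 and OOV surfaces at rate
  0.02 per position. Length is drawn per group × timepoint from the study's
  word-count distributions (baseline 70.6 ± 14.9 / 68.4 ± 30.3; follow-up
  70.0 ± 12.4 / 52.1 ± 19.8), truncated at ≥ 5.
* **Calibration.** Mean ASW-F is an increasing function of `p_stay`;
  `calibrate_p_stay` does monotone bisection with common random numbers.
  Cohort generation instead builds, per group × timepoint, a 21-point
  calibration curve (geometric spacing in 1 − p, where the response is
  steepest) and refines each group anchor with two Newton corrections
  against 2,500-transcript simulations, landing group means within ~0.002
  of their targets (baseline 0.334 HC / 0.352 FES; follow-up shifted by the
  group mean changes −0.008 / +0.020). Subject heterogeneity comes from a
  latent per-subject ASW target whose spread is the table SD minus the
  variance contributed by averaging 3 noisy transcripts; subject targets
  are mapped to `p_stay` through the curve around the refined anchor.
* **Covariates.** Clinical, cognitive and demographic variables are drawn
  from a Gaussian copula per group with targeted edges (e.g. latent
  ASW ↔ DSST −0.41 in patients, ASW ↔ Stroop accuracy −0.29 in controls,
  change-in-ASW ↔ change-in-negative-symptoms 0.592 among followed-up
  patients), marginals matched to the study's group means/SDs, then clipped
  to plausible ranges. Stroop raw counts are generated so the Golden
  interference of the raw counts equals the targeted IG; DSST oral/written
  bracket the targeted total. Medication: half of patients antipsychotic
  naive at baseline, the exposed half split between low and high
  D2-occupancy classes, doses log-plausible and independent of ASW (the
  study's null dose finding).
* **Seeding.** One integer seed fans out to per-subject and per-transcript
  substreams keyed by CRC-32 of (subject, picture, timepoint), so output is
  byte-identical across reruns and independent of generation order.
* **Matched null.** A null model keeps every mechanism but calibrates all
  groups to the HC similarity targets *under each group's own word-count
  distribution*. Equalizing `p_stay` itself is not a null here: the
  within-pair fraction of a full frame scales like 1/n, so the patient
  group's larger length dispersion raises its mean ASW-F at fixed `p_stay`
  (measured false-positive rate 14%); equalizing the similarity level—the
  actual null hypothesis of the group test—brings it to ~1–2%.

**What passing tests show, and what they do not.** The generator produces
the right group means, SDs, cohort geometry (82 subjects, 246 baseline and
99 follow-up speech samples), and latent correlation structure, so it
validates the scoring and inference machinery end to end. It does not
produce syntax, topic flow, disfluencies, rater behaviour, or any
relationship between word identity and meaning; within-transcript
similarity noise is dominated by run-structure and length variance, which
attenuates observed covariate correlations relative to their latent targets
(by roughly half at the default settings). Results on synthetic cohorts
therefore say nothing about effect sizes in real speech — only that the
pipeline recovers what the generator encodes.

**Validation problem sizes.** The recovery study uses 200 replicate
cohorts (each 82 subjects × 3 baseline descriptions) per condition and a
BF10 ≥ 3 detection threshold; oracle-equivalence checks use 1,000 random
sequences of length ≤ 50 and fixed (t, n) / (r, n) grids; credible-interval
coverage uses 500 simulated null datasets of n = 20. At the calibrated
group difference (0.018 at pooled SD ≈ 0.030, n = 36/46) the pooled-t
noncentrality is ≈ 2.7 against a BF10 = 3 threshold of t ≈ 2.45, so the
expected detection rate sits near 0.6–0.7 — detection at these sample
sizes is genuinely borderline, and replicate rates vary by a few points
across seeds.

## Known limitations

* The exact upstream stop-list and its casing rule are unknown; both are
  exposed as configuration and recorded in outputs, but absolute ASW values
  are not comparable across stop-list choices.
* Summary-statistic Bayes factors inherit the rounding of the printed
  means/SDs; they are flagged `rounded_input` and should be compared with
  tolerances.
* The ANOVA effect-size interval (η² via conjugate draws) is a pragmatic
  summary, not the exact marginal posterior under the g-prior.
* CHAT support covers main-tier extraction and common inline codes, not the
  full CHAT specification.
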