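# Methods

`lipidvote` implements a direct-infusion ultra-high-resolution FTMS (DI-FTMS)
lipidomics workflow for stable-isotope-resolved studies: consensus peak
detection across replicate scans, isotopologue-resolved elemental-formula
(EMF) assignment with positive-mode adducts, cross-sample EMF voting into
consensus features (sudo_EMFs), natural-abundance correction, and
category-level differential statistics. Because direct infusion provides no
chromatographic separation, identification rests entirely on exact mass,
isotopologue structure, and cross-sample consistency — which is what every
stage below is built around.

## Synthetic studies

Raw DI-FTMS data for a study of this design is rarely shareable at desk
scale, so the package ships a first-class generator that produces complete
studies (centroided scans, metadata, ground truth) with the statistical
structure the analysis assumes. The default design is 30 samples = 2
conditions × 3 block groups × 5 replicates, with the labeling scheme assigned
per block group (group 1 unlabeled, group 2 ¹³C, group 3 ¹³C+¹⁵N), emulating
a mixed-labeling infusion study of about thirty samples after outlier
removal. Scan count per sample and any outlier rule are configuration knobs,
not inferred quantities.

Abundances follow a hierarchical log2 model: an entry-level baseline
N(20, 2²), a per-category case-vs-control shift (the configured effect), and
per-(entry, sample) biological noise N(0, 0.5²). Each entry appears as one
randomly weighted adduct ([M+H]⁺ 70%, [M+Na]⁺ 15%, [M+NH₄]⁺ 10%, [M+K]⁺ 5%),
with a secondary adduct in 30% of sample-entries so the voting stage's
same-formula/different-adduct path is exercised. Isotopologues of labeled
samples follow a two-pool model: 70% pre-existing material with a
natural-abundance envelope, 30% newly synthesized material whose traced
element draws at 25% per-atom enrichment, rendered to full binomial depth.
Measurement noise is Gaussian per-scan m/z error (2 ppm), multiplicative
log-normal intensity noise (CV 0.2), and Bernoulli peak dropout (10% per
peak per scan). Everything is a pure function of the seed.

What the generator does *not* emulate: profile peak shapes, resolution- and
space-charge-dependent mass error, in-source fragmentation, chemical noise
and contaminant series, negative mode, or multiply charged species. Passing
tests therefore demonstrate correctness of the algorithms under the stated
statistical assumptions, not instrument-level robustness.

A statistics-level shortcut (`simulate_emf_table`) renders the same abundance
model directly as an EMF × sample table for studies of the differential
machinery, where the spectral stages would add runtime but no information;
replicate-based statistics below use it at 30 samples × 115 library entries.

## Consensus peaks

Scans are thresholded, rescaled so every scan's TIC equals that of the
median-TIC scan (lower median for even counts), and pooled; peaks are
clustered by ascending m/z against the running intensity-weighted cluster
mean at 5 ppm. Pooling before clustering makes the result invariant to scan
order. "Normalization to a median scan" is interpreted as TIC rescaling to
the median-TIC scan — the simplest reading; a quantile-based alternative was
considered and rejected as underdetermined. Consensus m/z is the
intensity-weighted mean and consensus intensity the plain mean over the
scans in which the peak is present (zeros excluded).

## Formula assignment

Candidate formulas come from a pre-enumerated cache over C/H/N/O/P with
default limits C ≤ 130, H ≤ 230, N ≤ 7, O ≤ 28, P ≤ 3 and [M+H]⁺ m/z ≤ 1400,
sorted by neutral mass so lookup is a binary search (a linear-scan oracle is
retained for equivalence testing). Sulfur is excluded from the alphabet:
the cache limits define the search space and list only these five elements.
Ring-plus-double-bond and H ≤ 2C+N+2 plausibility filters exist but default
off, so the e-value competes against the full combinatorial space.

Every consensus peak within 5 ppm of a cache formula's adduct m/z seeds a
candidate; isotopologue chains allowed by the sample's labeling scheme
(natural ¹³C always; tracer ¹³C, ¹⁵N, ²H per scheme) are extended by exact
spacings to other peaks. Mixed-isotope combinations are not chained — each
series is a single-isotope ladder, which keeps the search linear and is
sufficient for the envelope depths the quantification uses.

The e-value is this package's own construction:

    e = 1 − (∏ᵢ exp(−zᵢ²/2))^(1/k) · α^m,   zᵢ = ppm deviation / σ₀

with k matched peaks, m expected-but-missing isotopologues (natural relative
intensity ≥ 5% of the monoisotopic peak), and α = 0.5. The geometric mean
makes the score an evidence *quality* measure: additional well-matching
isotopologues can only help, never hurt. σ₀ defaults to the 5 ppm match
window (a deviation at the window edge scores z = 1) because consensus m/z
values are scan-averaged and systematically more precise than single-scan
readings; calibrating σ₀ to raw per-scan noise would push correct
assignments over the e ≤ 0.1 retention cutoff. Candidates with e ≤ 0.1 and
monoisotopic m/z ≤ 1400 are kept. Formulas with any library classification —
lipid category or decoy metabolite — score 2·(1−e), unclassified formulas
1−e. Classification is exact element-count lookup against the bundled
library (100 lipids across FA/GP/PK/PR/SP, 15 metabolite decoys);
substructure-based classification is out of scope.

## Natural-abundance correction and labeled fractions

For a vector of observed intensities over tracer shifts 0..k, the correction
matrix's column j is the truncated natural-abundance envelope of a species
with j tracer substitutions (j traced atoms no longer draw from natural
abundance); tracer-only intensities are recovered by non-negative least
squares. The system is lower-triangular and well-conditioned for any formula
in practical range; noise-free roundtrips recover inputs to ~1e-16 (tested
at 1e-8). For the ¹³C+¹⁵N scheme the correction axis is ¹³C, the dominant
tracer; ¹⁵N natural abundance enters through the envelope columns. With only
the monoisotopic species observed (k = 0) the correction is the identity.
The labeled fraction is Σ(shift ≥ 1)/Σ(all), the standard labeled/total
species ratio; an all-zero vector returns NaN.

## EMF voting

Within a sample, candidates sharing any matched peak — or the same base
formula under different adducts — union into a group_EMF (connected
components). Across samples, sudo_EMFs are built by iterative seeded
extraction: the formula with the highest cross-sample summed score
(per-sample best score, summed) seeds a sudo_EMF that takes, per sample, the
seed's candidates plus unconsumed candidates one peak-sharing hop away; the
extraction repeats on the remainder. This realizes the iterative
intersection-union idea while guaranteeing that every candidate belongs to
exactly one sudo_EMF and that two genuine features bridged by a shared decoy
formula cannot cannibalize each other — a failure mode we observed with
naive transitive merging, where a single chain-extension artifact linking
two lipids caused one to lose members wholesale.

Per sudo_EMF, formulas within 90% of the maximum summed score are retained.
Samples without a retained formula are rescued only if their best candidate
matches the cross-sample consensus in monoisotopic m/z (within the
labeling-group cutoff) and reproduces the exact relative intensity ordering
of the top-3 isotopologues, per adduct — adducts are never pooled, since the
same isotopologue under H⁺ and Na⁺ sits ~22 Da apart. m/z cutoffs are the
95th percentile of per-isotopologue cross-sample ppm standard deviations
within each labeling group, floored at 0.5 ppm; the maximum over groups is
applied study-wide. Isotopologues whose cross-sample spread exceeds the
cutoff lose their most deviant observations (never below two), and
candidates that lose their monoisotopic peak are removed, cascading to
formula and sudo_EMF removal when required peaks are gone.

sudo_EMFs sharing at least 50% of their peaks — denominator: the smaller
peak set, the most permissive consistent reading — are merged and voting
repeated to a fixed point; the peak footprint used for overlap is that of
the *retained* formulas, so losing bridge candidates do not create spurious
overlap. After merging, at most one member per sample survives (higher total
score wins), which keeps quantification well-defined. Lipid categories are a
plurality vote over the retained formulas' category sets after discarding
non-lipid and non-classified votes; ties report "multiple". The sudo_EMF
m/z is the minimum member isotopologue m/z across samples.

## Quantification and statistics

Member samples contribute the consensus intensities of their best retained
candidate's matched isotopologues. The IMF × sample matrix is normalized per
sample by its median peak intensity (so each sample's median is exactly 1),
missing cells are imputed to half the smallest normalized value in the study
(a single global threshold), IMF intensities are summed per EMF, and the
result is log2-transformed. A cell is flagged imputed when every member IMF
of that EMF was imputed in that sample.

Differential abundance is a per-EMF linear model of log2 intensity on
condition with labeling status (labeled vs unlabeled) and block group as
blocked covariates. Residual variances are moderated across EMFs by
empirical Bayes (method-of-moments on log variances via digamma/trigamma,
inverse-trigamma by Newton iteration), giving a moderated t on the condition
coefficient; plain OLS is available by configuration for cross-checking.
Raw p ≤ 0.1 is the per-EMF significance call. In the default design labeling
is aliased with block group; aliased *blocked* covariates are dropped with a
log note, while an aliased condition term is a hard error naming the terms.

Fold changes are the ratio of linear-scale averages (case over control),
log2-transformed afterwards; a difference-of-log2-means alternative is a
configuration switch. For each lipid category (rows labeled "multiple",
non-lipid, or non-classified removed first), EMFs split into positive
(log2FC > 0) and negative (≤ 0) and an exact two-sided binomial test against
a 50/50 null is Bonferroni-corrected over the tested categories.

EMF–EMF association is Pearson correlation over co-observed (non-imputed)
samples, multiplied by IC·ICon where IC = co-present/n (information content)
and ICon = (co-present + co-missing)/n (information consistency). The
multiplicative IC·ICon weighting is this package's concrete realization of
an informally specified weighting; pairs with fewer than three co-present
samples are reported missing.

## Numerical and design choices

- Masses and natural abundances come from the NIST tables in pyteomics;
  adduct masses subtract the electron mass.
- Envelope probabilities renormalize after truncation and must sum to 1
  within 1e-12; degenerate (all-zero) truncations raise.
- Greedy consensus clustering and single-linkage agree only on separated
  data; the equivalence test generates peaks either well within or well
  beyond tolerance.
- All voting loops process items in canonical (formula string, sample id)
  order, making results invariant to input permutation; ties in the
  extraction heap break on the formula string.
- Problem sizes for the shipped studies: the full-pipeline study uses 60
  library lipids plus 15 decoys, 30 samples, 3 scans per sample, and the
  reduced cache (C ≤ 60, H ≤ 120, N ≤ 3, O ≤ 15, P ≤ 2, m/z ≤ 1000,
  ~1.4M formulas); replicate statistics use the statistics-level generator
  at 30 samples. These sizes make a complete analysis a matter of minutes
  on one core while leaving every stage's behavior measurable.

## Known limitations

- The e-value is a calibration-free heuristic, not a probability; its 0.1
  cutoff is meaningful only relative to σ₀.
- Exact-formula classification cannot separate isomeric lipids; category
  votes inherit that ambiguity ("multiple").
- Median normalization carries composition bias when a large fraction of
  the signal shifts; with category-level shifts on ≤ 20% of features the
  bias is negligible.
- NA correction assumes the tracer and natural substitutions are
  independent and the traced element dominates the observed shift axis.
- Negative mode, multiple charging, MS/MS evidence, and retention time are
  out of scope.
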