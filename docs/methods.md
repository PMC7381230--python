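# Methods

`seroglycan` implements the computational chain of a serum anti-glycan
antibody study: glycan-array serology against a composition-annotated
oligosaccharide library, per-glycan differential reactivity between serum
groups (healthy control, ulcerative colitis, Crohn's disease), and the
follow-up microbiome experiments that trace elevated anti-fucose
reactivity to lectin- and IgG-captured gut bacteria. This note records
the models, the parameter choices, and what the synthetic studies do and
do not establish.

## Array processing

A scanned array exports, per spot, the mean foreground fluorescence and
the mean fluorescence of a local background annulus (spot 110 µm,
annulus 330 µm by default; geometry is metadata only). Processing is:

1. per-spot background subtraction, `net = FG − BG` (may be negative);
2. arithmetic mean over replicate spots (four expected; deviations warn);
3. clamping of non-positive means to 1 RFU;
4. `log2(RFU)` of the clamped mean.

Cells of the resulting samples × glycans reactivity matrix are therefore
never negative. Two edge decisions: means in (0, 1) — positive but below
the clamp constant — are kept at step 3 and floored to 1 at the log step,
so the non-negativity contract is enforced exactly once; and subtraction
precedes averaging (the order only matters when clamping intervenes).

## Composition grammar and subgroups

Array features are annotated only by monosaccharide composition —
hexose (H), N-acetylhexosamine (N), fucose (F), sialic acid (S) — e.g.
`H4N2F3`, optionally with a trivial-name alias (`H2F1 (3-FL)`),
slash-separated alternatives (`H6N4F4/H7N5F2`) or the literal `unknown`.
Decoration classes (undecorated / fucosylated-only / sialylated-only /
both) and count bands (F1, F2–F4, >F4; S1, S2, >S2) drive all subgroup
summaries. Two conservative rules:

* an ambiguous multi-alternative feature joins a subgroup only when every
  alternative agrees on it, otherwise it is excluded from that subgroup;
* `unknown` features stay in whole-array summaries but never in
  decoration subgroups.

Bands beyond the classic figure range (more than four fucoses, more than
two sialic acids) are reported separately and never merged into F2–F4/S2.

## Group comparisons

Subgroup comparisons across the three serum groups use one-way ANOVA
with Bonferroni-adjusted pairwise t-tests on the pooled within-group
variance, or Kruskal–Wallis with Dunn's large-sample z from tie-corrected
mean ranks — in both cases restricted to the two selected pairs
ctrl-vs-UC and ctrl-vs-CD (Bonferroni factor exactly 2; UC-vs-CD is never
tested). Degenerate inputs (all values identical) return p = 1 with a
flag rather than an error.

## Differential reactivity (moderated t)

Each glycan gets a two-group linear model on log2(RFU): logFC is the
difference of group means, and the pooled residual variance `s_g²` has
`d = n_A + n_B − 2` degrees of freedom. Because per-glycan variance
estimates are noisy at serology sample sizes, an empirical-Bayes prior
`s_g² ~ s₀² · scaled-F(d, d₀)` is fitted across all glycans by matching
the mean and variance of `log s_g²` (digamma/trigamma moment equations;
the trigamma inversion uses Newton iteration). The posterior variance

    s̃_g² = (d₀·s₀² + d·s_g²) / (d₀ + d)

yields the moderated `t̃_g = logFC_g / (s̃_g·√(1/n_A + 1/n_B))` with
`d₀ + d` degrees of freedom. When the observed spread of `log s_g²` is no
larger than its pure sampling component the prior is degenerate
(`d₀ = ∞`) and every posterior variance equals `s₀²` (the statistic is
then referred to a normal). If every variance is zero, moderation falls
back to the ordinary pooled t with a warning. `d₀ = 0` recovers the
ordinary t exactly.

The hit rule mirrors standard reporting for these arrays: |logFC| > 2
(strict) and raw p ≤ 0.05 (inclusive), split by direction and sorted by
|logFC|. Raw p is used deliberately — published hit tables for such
arrays include p = 0.05 entries that would not survive multiplicity
correction over ~220 features — while Benjamini–Hochberg adjusted values
are always computed and reported alongside.

## Clustering and isotype correlation

Sample clustering uses the pairwise Pearson correlation matrix, distance
`1 − r`, and complete-linkage agglomeration. The agglomeration is
implemented in-package rather than delegated, because the merge order
under ties is part of the contract: ties are broken by the
lexicographically smallest pair of cluster representatives (a cluster's
representative is its smallest original sample index), making the merge
sequence reproducible and testable against a brute-force re-scan oracle.
A constant sample vector is a fatal error (its correlations are
undefined). IgG–IgM agreement is the per-sample Pearson r across
glycans; flow-cytometry MFI values are normalized by each serum's IgG
concentration (fluorescence per mass/volume).

## Sorted-fraction enrichment

OTU counts from sorted (lectin-positive or IgG-positive) and matched
unsorted samples are converted to percentages of total bacteria, and
aggregated to a rank by summing counts over shared labels; OTUs
unassigned at that rank aggregate under their lowest assigned ancestor
(`f:Lachnospiraceae;g:unclassified`), so totals are conserved exactly.
Fold enrichment is the ratio of sorted to matched-unsorted percentage
with an additive pseudo-proportion equal to one read in the smaller of
the two libraries (default; configurable), which keeps zero-denominator
ratios finite and shrinks low-depth noise. A taxon absent from both
fractions sits exactly at 1.

Screening is threshold-inclusive ("at least 1.5-fold", ≥) per sorted
replicate and combined by majority across replicates. The candidate
intersection keeps taxa that (a) pass the lectin screen, (b) exceed the
threshold strictly ("more than 1.5-fold", >) for the IgG-capture fold of
at least one serum group — group folds are medians across that group's
sorted samples — and (c) have a higher median fold under CD-serum capture
than under healthy-control capture. The per-group-median form of (b) was
chosen because a CD-specific antigen is, by construction, poorly captured
by control sera: a median over all sera would bury exactly the taxa the
intersection exists to find. Candidates are by construction a subset of
both screens, with per-criterion evidence attached. Alpha richness is
the raw count of OTUs with at least one read; no rarefaction is applied,
so depth should be reported alongside.

## qPCR

Targets are quantified relative to a total-bacteria amplicon on the same
plate by `2^(−ΔCt)`, assuming doubling per cycle; technical replicates
are averaged on the Ct scale before the difference. `log2` of the
relative quantity is exactly `−ΔCt`. Two-group comparisons (sorted vs
unsorted) use the classic equal-variance Student t.

## Synthetic studies: what they emulate

The generator produces every input from explicit parameters and a seed
(identical config + seed ⇒ byte-identical files).

**Array studies.** Glycan baseline `b_g ~ N(9, 1.2)` on the log2(RFU)
scale (median raw signal ≈ 500 RFU, realistic for serum IgG at 1:100-ish
effective dilutions); serum-wide offset `a_i ~ N(0, 0.25)` (≈ ±20%
intensity scale between sera — modest on the log scale, enough to make
per-serum patterns visible without coupling per-glycan tests through a
dominant shared term); residual noise sd 1.0; a planted CD-specific shift
δ (default 1.5 log2 units) on a decoration subgroup (default the F2–F4
band); group sizes 20/17/23 (ctrl/UC/CD). The IgM channel shares the
glycan-varying signal at coupling ρ (default 0.8) plus independent
matched-variance noise, so the per-serum IgG–IgM Pearson r concentrates
near ρ. Spots: foreground = 2^level + lognormal local background (mean
100 RFU, CV 0.2) + Gaussian spot noise (sd 10 RFU), four replicates. The
default class mix (20% undecorated, 25% F1, 25% F2–F4, 20% sialylated,
10% fucosylated-sialylated over 220 features) is a configurable stand-in,
not a published library inventory.

**Sorting studies.** A fermenter-like community of 24 OTUs (a planted
3-species Bacteroides genus at 6% plus 21 background taxa) with
per-sample proportions drawn from a Dirichlet (concentration 300 × base
proportions). Unsorted counts are multinomial at depth 2×10⁴; sorted
fractions re-weight proportions by per-taxon capture probabilities (0.6
for planted taxa under lectin and CD-IgG staining, 0.2 elsewhere —
capture ratio 3). Three lectin replicates and six IgG-sorted samples per
serum group, each with a matched unsorted sample. The expected lectin
fold of the planted genus is 0.6/0.224 ≈ 2.7 (> 1.5) and ≈ 0.9 (< 1.5)
for background taxa, so the screen is separable but not trivially so at
the default depth.

**qPCR.** `Ct_total = c₀ − log2(T)` and `Ct_target = c₀ − log2(T·p) +
N(0, sd)`, so the expected recovered relative quantity equals the true
template proportion p.

**What passing does not show.** The generators draw from well-behaved
parametric families: Gaussian log-scale noise, lognormal backgrounds,
multinomial counts from Dirichlet communities, and a single planted
effect. Real arrays have spatial artifacts, saturation, batch effects
and glycan-specific cross-reactivity; real 16S data carry PCR/primer
bias, contamination, compositional coupling between many simultaneously
shifted taxa and database-dependent taxonomy. Parameter recovery here
validates the pipeline's correctness and calibration under its stated
model, not robustness to those failure modes, and no claim about the
original patient cohort's numbers is implied.

## Validation scale

The bundled end-to-end checks run 200 array studies per condition for
subgroup-recovery and calibration checks, 100 sorting studies for
candidate recovery, 50 random matrices against the moderated-t
closed-form oracle, and 200 random instances against the clustering
oracle; `scripts/acceptance.py` reports the same quantities at 50/30
studies per condition. These sizes give comfortable Monte-Carlo margins
for every bound checked (e.g. the null false-positive rate is estimated
from 44,000 pooled per-glycan tests).

## Known limitations

* The differential model is a two-group contrast; no covariates.
* Dunn's z uses the normal approximation; no exact small-sample tables.
* Complete-linkage is O(n³) with the deterministic tie-break; fine for
  cohort-scale sample counts, not for thousands of samples.
* The fold-enrichment pseudocount is additive on the percentage scale;
  other shrinkage choices (e.g. Bayesian posterior proportions) are not
  implemented.
* Aggregation keys require rank-prefixed lineages; bare lineage strings
  aggregate under `unclassified` fallbacks.
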