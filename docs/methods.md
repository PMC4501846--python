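# Methods

## Data model

All quantities are SILAC ratios from a triple-label stimulation
time-course: light = unstimulated control, medium = 5 min, heavy = 15 min
of receptor stimulation. Tables carry linear-scale, strictly positive
ratios per replicate and channel (M/L and H/L); log₂ transformation
happens only inside the statistics. Missing ratios are represented as
absent values throughout — never as zero — because a zero ratio is a
valid-looking but wrong number, whereas a missing cell simply removes
that replicate from medians, supports and correlations.

Positions are 1-based on the protein sequence. A site table holds one
modification type (phospho on S/T/Y or di-Gly on K); localization
probability and PEP live in [0, 1].

## Interactor calling

The empirical-background procedure assumes that the large majority of
proteins in a pull-down are nonspecific binders centered at log₂ ratio 0.
Per channel:

1. each protein is summarized by the median of its log₂ ratios across the
   replicates in which it was quantified;
2. proteins are ranked by this summary (stable tie-break on protein ID)
   and the lowest floor(0.9·n) form the background set;
3. the null location is the median of the pooled per-replicate log₂
   ratios of **all** quantified proteins, the null spread the sample SD
   (n−1) of the pooled ratios of the **background** proteins;
4. the cutoff is median + `sd_multiplier`·SD, default multiplier 2.

An interactor must, in at least one channel, have (i) a linear ratio at
or above `fold_threshold` (default 2) in at least `min_replicates`
(default 2) replicates of that channel, **and** (ii) a median log₂ ratio
strictly above that channel's cutoff. Per-channel enriched flags require
that channel's own (i) and (ii), which is what assigns proteins to time
points in the Venn partition. A protein quantified in fewer than
`min_replicates` replicates of a channel cannot pass that channel, and
down-enrichment is deliberately not called — the procedure has no
negative class.

Two design points deserve emphasis. The SD is an observation-level
spread, while criterion (ii) tests a median of up to four replicates; the
median's sampling SD is roughly half the single-observation SD at four
replicates, so the cutoff sits several *median*-SDs out and the
background contributes only ~10⁻³–10⁻⁴ of proteins under Gaussian noise.
This, combined with the replicate-support rule, is what gives the
procedure its selectivity (measured in the recovery benchmark:
sensitivity ≈ 1.0, empirical FDR ≈ 0.02 under the default simulation).
Second, criteria are combined with AND; the replicate-support rule can
only shrink the set passing the cutoff rule, which the null-calibration
test asserts directly.

No ratio re-normalization is performed — input ratios are assumed
normalized upstream. Scale equivariance holds by construction: rescaling
one channel shifts its median and cutoff equally and leaves the called
set unchanged.

## Site confidence filters

Kept iff localization probability ≥ 0.75 AND score ≥ 40 AND PEP ≤ 0.01,
all boundaries inclusive, checked in that order for deterministic
rejection reasons. The same score filters are applied to di-Gly sites by
default (`apply_score_filters_to_digly`, configurable), which is the
conservative choice when a separate di-Gly threshold set is not
specified. Di-Gly sites must be internal in the peptide: trypsin cannot
cleave C-terminally of a di-Gly-modified lysine, so a C-terminal di-Gly
lysine is an in-vitro artifact. The filters are idempotent and mutually
order-independent, and kept ∪ rejected is always the input.

## Regulation and dynamics

Per time point a site's summary is the median linear ratio across
replicates; up at ≥ 2, down at ≤ 0.5 (inclusive). The defaults satisfy
the duality `down_fold = 1/up_fold`, so inverting every ratio swaps up
and down counts exactly — a property test guards this.

The dynamics label is a deterministic function of the class pair and the
between-time-point ratio, replacing model-based profile clustering with
an auditable rule (precedence order):

| label | rule |
|---|---|
| early-transient | up at 5 min AND (not up at 15 min OR ratio₅/ratio₁₅ ≥ `transient_drop`) |
| sustained | up at both, ratio₅/ratio₁₅ < `transient_drop` |
| late | up only at 15 min (5 min unchanged or unquantified) |
| down-regulated | down at either, up at neither |
| unregulated | no up or down call at either point |
| mixed | anything else (down then up) |

`transient_drop` defaults to 2.0, chosen so that the canonical rapid
transient profile — 19.5-fold at 5 min decaying to 2-fold at 15 min —
lands in early-transient while a persistent 20.5 → 22-fold profile is
sustained. Class pairs with no up/down call and at least one missing
channel are reported as unregulated rather than mixed: absence of
evidence is not evidence of opposite regulation.

The residue-class summary (Tyr vs Ser/Thr) reports, per time point, the
number of quantified/up/down sites and the arithmetic mean linear fold
change, by default over the up-regulated subset (the convention behind
"average increase" figures), optionally over all quantified sites.

## Rank-sum test

For two tie-free groups with ≤ 8 observations each, the p value is
computed by full enumeration of all C(n+m, n) group assignments of the
pooled values; the two-sided p is twice the smaller tail probability of
the observed Mann–Whitney U, capped at 1 (so identical groups give
p = 1). Larger or tied inputs use the Normal approximation with tie and
continuity correction (via scipy). For tie-free groups up to n = 8 the
approximation stays within 0.05 absolute of the exact value, which a test
asserts on random inputs.

## Integration and enrichment

A protein enters the co-regulation table when it carries at least one
up-regulated site (any time point) in either PTM layer; it is
co-regulated when both layers contribute. Signalosome membership is an
annotation, not a requirement. Enrichment is a one-sided hypergeometric
upper tail per term, P(X ≥ k) for X ~ Hypergeom(N, K, n), with
Benjamini–Hochberg q values across exactly the tested (k ≥ 1) terms —
the behavior of common GO tools. The default universe is the set of
proteins quantified in the relevant layer: the only universe the pipeline
can know, and standard enrichment practice. No ontology-graph
propagation is performed; annotations are a flat two-column table.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not mass spectra. For the pull-down table: each observed log₂ ratio is
the protein's true effect (0 for background binders; configurable log₂
effects per channel for interactors, default 2.0) plus independent
per-observation noise from two sources — background-binding variability
`sigma_background` (default 0.5) and technical replicate noise
`sigma_replicate` (default 0.25). Missingness is independent Bernoulli
dropout per (protein, replicate, channel), default 0.1. Defaults mirror
the study design: 3,000 proteins, 4 replicates, 5% interactors.

Noise is deliberately independent across replicates: a persistent
protein-specific binding bias would be statistically indistinguishable
from a true interaction, and modeling it would make any background
procedure's false discoveries irreducible. This is the generator's main
idealization — real pull-downs do contain such proteins (and heavier
than Gaussian tails), so the recovery numbers measured here are an upper
bound on real-data performance, and the published log₂ cutoffs
(1.36/1.86 in the motivating dataset) are correspondingly higher than
the ≈1.1 the Gaussian simulation produces. The Gaussian choice itself is
a modeling decision; the underlying studies do not state a background
distribution.

For PTM sites: ~10,000 phospho and ~6,000 di-Gly sites over 2
replicates, drawing protein IDs from a shared pool so cross-layer
co-regulation occurs. 4.1% of phospho sites are on Tyr (the remaining
split S:T = 85:15); 20% of sites are regulated, partitioned over dynamics
classes (early-transient 0.35 with effects (4.3, 1.0) log₂ — a ≈19.7-fold
spike decaying to 2-fold; sustained 0.35 at (2.0, 2.0); late 0.20 at
(0.0, 2.0); down 0.10 at (−1.5, −1.5)), each site's persistent effect
scattered around its class mean with `sigma_site` = 0.3. Unregulated
sites scatter per observation with SD `sigma_background` = 0.4, which
places the 2-fold cutoff near median + 2.5 SD of the unregulated
distribution — the calibration the regulation thresholds assume.
Quality scores are drawn so that configurable fractions fail each filter
(10% localization, 5% score, 5% PEP, 5% C-terminal di-Gly); truth labels
(regulation class per time point from the noiseless site effect at ±1
log₂, the drawn dynamics class, and a passes-quality flag) are fixed
before noise is added.

Determinism: one integer seed drives a single generator instance; the
same config reproduces tables byte-for-byte.

## Numerical choices and degenerate inputs

* Medians use numpy's midpoint convention; background ranking breaks
  ties by (summary, protein ID) so exactly floor(0.9·n) proteins enter
  the set regardless of duplicates.
* Background fitting requires ≥ 3 quantified proteins and a background
  set of ≥ 2; the rank-sum test rejects empty groups; replicate
  correlation requires ≥ 3 complete pairs. All raise typed errors rather
  than returning NaN.
* Criterion (ii) uses a strict inequality ("greater than" the cutoff);
  all printed filter and fold thresholds are inclusive.
* TSV floats are written with `repr`, giving shortest-round-trip decimal
  representations that are identical across platforms; the JSON report
  has sorted keys and no timestamp, so repeated runs are byte-identical.
* Problem sizes in tests and the acceptance script (20 simulations of
  3,000 proteins for calibration and recovery; 200 random tables for
  oracle equivalence; the full N ≤ 30 hypergeometric grid) were chosen to
  make sampling error a small fraction of the tested tolerances while a
  full run stays in the tens of seconds.

## Known limitations

* No persistent protein- or site-specific biases, no heavy-tailed ratio
  distributions, no intensity-dependent missingness — passing recovery
  tests bound ideal-case, not real-data, performance.
* SILAC ratio normalization is assumed done upstream; a per-channel
  median-centering switch exists for un-normalized inputs but is off by
  default and is no substitute for proper upstream normalization.
* Localization variants at the same position are distinct records; no
  collapsing or re-scoring of site localization is attempted.
* The enrichment module knows nothing about ontology structure; parent
  terms must be materialized in the annotation table if wanted.
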