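# Methods

## Guide alignment and the multi-target filter

Protospacers are 20-nt ACGT strings. Alignment is exhaustive by design:
every offset of every contig is compared on both strands, keeping windows
with at most two mismatches whose adjacent PAM — the three bases immediately
3′ of the protospacer on the hit strand — matches NGG ("N" matches any
base). Coordinates are reported 0-based half-open on the forward strand.
Hits whose PAM window would run past a contig end are discarded. There is no
index structure to fall out of sync with the definition; on toy genomes
(tens to hundreds of kilobases) the numpy-vectorized scan costs milliseconds
per guide.

Mismatch positions are indexed 1..20 from the PAM-distal end, so "the two
most PAM-distal nucleotides" are positions {1, 2}. A guide is flagged
multi-targeting iff it has (a) two or more perfect hits, (b) a perfect hit
plus any one-mismatch hit, or (c) a perfect hit plus a two-mismatch hit with
both mismatches in {1, 2}. Because any one- or two-mismatch hit necessarily
occupies a different locus than a perfect hit, the "distinct locus" reading
of rules (b) and (c) is automatic. Guides with no perfect genomic hit are
dropped with reason "no perfect hit": screen libraries are designed against
the reference, so a guide that no longer matches it perfectly cannot be
attributed to a gene with confidence. Retained guides must hit exactly one
gene interval; loci overlapping two or more genes (read-through-style loci)
and intergenic loci are dropped. Genes with fewer than three retained guides
are excluded from scoring.

Gene scores are the per-line arithmetic mean of retained-guide log-fold
changes. This is deliberately *not* a CERES-style estimator — no copy-number
correction and no guide-efficacy modelling — but its outputs occupy the same
role, and pre-computed gene-effect matrices can be supplied directly in
tables mode. A line's score is missing when fewer than three of the gene's
guides have data there (real screens rarely have missing LFCs; the rule
exists for robustness). Screen QC is average precision over
reference-labelled genes ranked by ascending score, computed per line and
averaged.

## Binarization

The pooled score distribution is fit with 1-D Gaussian mixtures, k = 1..5,
each with multiple EM restarts (default 10, tolerance 1e-6); the k
minimizing AIC = 2(3k−1) − 2 logL is kept (free parameters: k means, k
variances, k−1 weights — identical to scikit-learn's count for full
1-D covariances). Components are identified by sorted means, never by fit
order, to sidestep EM label switching.

The essentiality threshold τ is the equal-weighted-density point between the
lowest-mean ("essential") and second-lowest ("moderate fitness defect")
components — equivalently the point of equal posterior responsibility
between them. It is located by scanning 2049 grid points between the two
means for sign changes of the weighted-density difference and bisecting the
crossing nearest the moderate mean to |Δ| < 1e-8. A mixture boundary could
alternatively be defined as the density minimum; the equal-responsibility
convention is the natural decision boundary of a mixture classifier and is
recorded in the fit metadata so downstream consumers can tell which rule
produced τ. Binarization is inclusive (score ≤ τ ⇒ essential); missing
scores stay missing. A sensitivity mode reruns the entire downstream
pipeline at user-supplied thresholds (e.g. −0.4 and −0.6) through
`threshold_override`.

Categories: never (0 essential lines), broadly (fraction ≥ 0.90), sometimes
(everything else). Decile bins over the nonzero fractions, per-line
essential counts and their median complete the summary.

## Paralogy annotation

Pair tables carry both directional protein-sequence identities (percent of
each gene's sequence matched in the other; asymmetric when lengths differ).
Filtering keeps pairs with both identities ≥ 20% and both genes in the
protein-coding universe. A gene's closest paralog is the partner in which
the largest percent of the gene's *own* sequence is matched — the
directional convention matching a per-gene "maximum percent matched"
summary — with ties broken by smallest partner symbol; the convention is
recorded in output metadata because min- or mean-direction definitions are
equally defensible. A pair is WGD if its unordered symbols appear on either
of two input WGD lists, SSD otherwise; a gene is WGD if it is in at least
one WGD pair regardless of SSD membership. Complex flags: either gene in
any complex; both genes in one common complex.

## Synthetic-lethality calling

A focal gene A1 is testable when it is sometimes essential with
fraction_essential ≥ 0.01 (inclusive, computed over lines with essentiality
data) and has at least one paralog with expression data. Two test families
are defined — closest (one pair per A1) and all (every expressed paralog) —
and BH-FDR is applied within each family separately, since the two designs
ask different questions and are reported separately. Per pair, a
pooled-variance two-sample t test compares A2 expression between
A1-essential and A1-non-essential lines (each stratum must have ≥2 lines
with expression; lines are intersected pairwise). A pair is putative SL when
q < 0.10 *and* mean A2 expression is lower in the essential stratum; the
direction is enforced post-hoc on the two-sided p rather than via a
one-sided test, reproducing the usual implementation of "significantly
lower at FDR 10%" (a one-sided option exists on the t-test wrapper).

Follow-ups run on flagged pairs only, with BH families restricted to the
evaluable flagged pairs: copy number uses the same stratified t test
(flag: p < 0.05, q < 0.10, lower CN in essential lines); nonsense mutations
use a one-sided Fisher enrichment of A2 nonsense calls in A1-essential
lines, restricted to pairs whose A2 is nonsense-mutated in ≥1 line. The
enrichment battery tests the SL flag against WGD/SSD, complex membership
(either and same), WGD within complex-member pairs and complex membership
within WGD pairs (all Fisher, sample odds ratios), plus t comparisons of
pair identity between SL and non-SL pairs overall and within subsets. Pair
identity is the mean of the two directional identities (the choice is
recorded in the report).

## Statistical kernel

Fisher p-values are two-sided by the point-probability method (one-sided
"greater" where enrichment is asserted); odds ratios are sample
cross-products ad/bc, ∞ when only bc vanishes and NaN when both products
do. The t test defaults to the pooled-variance Student form with a Welch
flag; zero-variance degeneracies are resolved explicitly (equal means →
p=1, unequal → p=0 flagged degenerate). Mann–Whitney is exact for tie-free
pooled samples of ≤12, normal-approximated with tie correction otherwise;
a pooled-constant sample short-circuits to U = n1·n2/2, p = 1. FDR control
is Benjamini–Hochberg throughout. The essentiality-category model
comparison is a multinomial (3-class) logit with intercept fit by Newton's
method; the likelihood-ratio statistic is 2(logL_full − logL_reduced) with
2 df per added feature. Complex over-representation is a one-sided
hypergeometric against a custom background, BH-corrected across complexes.
Standard tests are computed via scipy/statsmodels behind this module's
interface; the tests in `tests/` check them against independent enumeration
oracles on small totals.

## The synthetic cohort generator

The generator's defaults are the study conditions: 600 genes × 60 cell
lines, 61% of genes in paralog families (sizes 2–5 weighted 70/15/10/5%),
64% of pairs WGD, never/sometimes/broadly split 48/46/6%, 40 planted SL
pairs of which half are copy-number-driven.

Every gene carries a latent per-line state. Never genes are tolerated
everywhere; broadly genes essential everywhere; sometimes genes essential in
an exact per-gene fraction f ~ U(0.05, 0.6) of lines and
moderate-fitness-defect elsewhere; a planted SL focal gene A1 is essential
exactly in the lines where its partner A2 is in its low-expression state
(30% of lines) and tolerated elsewhere. Observed scores draw from the
state-matched component — N(−1, 0.2²) essential, N(−0.5, 0.15²) moderate,
N(0, 0.15²) tolerated — and guide log-fold changes add i.i.d. N(0, 0.1²)
guide noise. Expression is log2(TPM+1)-like Gaussian (high mean 6, low mean
3, sd 1): the SL test uses only mean differences, so the marginal scale is
immaterial. Copy number sits near 1 (log2-relative scale) with the planted
CN-driven A2s dropping to 0.5 in exactly the low-expression lines. Nonsense
mutations are Bernoulli(0.002) per gene-line, with an optional planted
enrichment pair. Pair identities are U[20, 100] except planted SL pairs,
drawn from U[60, 100] in both directions so the identity-vs-SL direction is
recoverable. Complex membership is sampled per pair with WGD pairs enriched
at a configured odds ratio (default 2.3), and one "housekeeping" complex of
broadly essential genes is always included for enrichment tests.

Planted SL pairs live in two-gene families only, making A2 automatically
A1's closest paralog, and are split between WGD and SSD strata at rates
solved (by bisection on the stratum odds) to realize the configured planted
odds ratio exactly at the integer-count level. The odds ratio recovered
from *called* SL pairs is mildly attenuated relative to the planted value
because the tested family also contains unplanted pairs; at ~600 testable
pairs the recovered mean sits near 2.0–2.3.

Two consequences of these defaults are worth knowing. First, the
equal-density boundary of the implied mixture sits near −0.75, where an
essential-state cell is called essential with probability ≈0.89 per line;
broadly essential genes (essential state in all lines) therefore fall below
the 90% broad cutoff in roughly half of draws, so the broadly category is
under-counted relative to truth while overall per-gene category recovery
stays ≥95% (broadly genes are only 6% of the cohort). Second, the pooled
mixture weights equal the expected *state occupancy* (≈0.21/0.27/0.52 for
essential/moderate/tolerated), not the raw category fractions; the
generator exposes the analytic expectation via `expected_state_occupancy`
and records the realized occupancy in the ground truth.

What the generator does not emulate: sequencing reads, guide-efficacy
variation, copy-number artefacts on guide counts (the motivation for
CERES-style correction), chromosome-arm CN segments, tissue lineages, or
correlated expression programs. Passing tests therefore demonstrate that the
pipeline recovers planted structure under idealized noise, not that the
biological effect sizes in real screens match these defaults.

## Problem sizes and determinism

The test suite and the acceptance script run cohorts of 120–1500 genes and
40–60 lines; the full default pipeline (600 × 60, mixture fit included)
completes in well under a minute on one CPU, and the toy-genome alignment
stage scales linearly in genome length × guide count. All randomness in a
run flows from a single integer seed through `numpy.random.default_rng`;
identical configs yield byte-identical artifacts, and reports serialize
with sorted keys so reruns are diffable.

## Known limitations

* The mean-of-guides scorer ignores copy-number-driven cutting toxicity;
  score matrices from corrected estimators should be preferred in tables
  mode when available.
* The SL test treats lines as exchangeable — no lineage covariates — and
  detects only pairwise buffering; higher-order family buffering and
  SL with non-paralogous partners are out of scope.
* Expression-low states are modelled as a clean bimodal mixture; shallow or
  graded repression shrinks power in ways the planted-recovery tests do not
  probe.
* The multinomial-logit comparison assumes nominal (unordered) categories;
  an ordinal model would use the never < sometimes < broadly ordering but is
  not implemented.
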