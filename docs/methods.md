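# Methods

## Scope and objects

The package compares retained calls from two open-source fusion callers
(labelled `ARR` and `SFU`) against a vendor reference caller (`REF`) on
per-sample targeted RNA-seq data, and against orthogonal single-gene assays
(break-apart FISH, fusion-probe FISH, RT-PCR, IHC). Calls are compared at
the level of normalized gene-symbol sets: no breakpoint arithmetic, no
transcript-isoform annotation, no HGNC alias resolution. Three event
classes exist — inter-gene fusion (≥2 partners), exon skipping and
intragenic deletion (1 partner each). Only fusions enter the caller
comparison, because the compared callers cannot emit single-gene events.

## Matching rules

**Pair keys.** The default policy is unordered: `PairKey(A,B) ==
PairKey(B,A)`. Break-apart FISH cannot resolve 5′/3′ orientation and the
callers are compared by the gene names they print, so orientation carries
no evidence here; ordered matching remains available as a config option. A
complex subject call (>2 partners) matches a reference pair when it
contains both partners.

**Reference verdicts.** One verdict per (sample, subject caller).
Reference-fusion-positive samples map to `confirmed` (some pair key
matches), `different` (subject called fusions, none match) or `missed`
(subject silent). Reference-negative and not-evaluable samples map to
`additional` or `negative_concordant`. Not-evaluable samples are screened
for additional calls like negatives (the open-source callers ignore the
vendor QC gate) but are excluded from the negative-concordance denominator,
which counts QC-passing reference-negative samples only. Samples whose only
reference events are exon skippings are excluded from the comparison
entirely.

**Assay verdicts.** Confirmation precedence: an exact-pair fusion-probe or
RT-PCR `fusion_confirmed` outranks a break-apart `translocated` on either
partner; an `unbalanced` break-apart pattern is reported as its own
category (rearrangement without guaranteed productive fusion); a call whose
partners are covered only by `negative` or `intragenic_rearrangement`
outcomes is `contradicted` — the intragenic pattern is deliberately
non-confirming, since it does not demonstrate the called partnership.
`not_done`/`not_assessable` outcomes are uninformative, and IHC is treated
as screening evidence only: it never confirms or contradicts on its own.

## Metrics

All fractions are stored as integer numerator/denominator pairs; rounding
to whole percent happens only at presentation, because stored precision
must exceed display precision. Sensitivity = confirmed /
reference-fusion-positive samples. Negative concordance = silent-subject /
QC-passing reference-negative samples; it is reported where specificity
would be, as no event-level truth exists on negative samples. PPV and NPV
carry an explicit construction label: `event_level` (PPV = confirmed events
/ (confirmed + additional events)) or `sample_level`; NPV is
sample-denominated in both (negative-concordant / (negative-concordant +
missed)). The two constructions are never silently mixed — they genuinely
differ whenever a sample carries several additional calls. Venn partitions
operate on sets of (sample, pair-key) tuples and always sum to the union
size. The depth/detection association uses the Wilcoxon rank-sum test:
exact enumeration when the pooled sample has ≤20 observations without ties,
tie-corrected normal approximation otherwise, with the method reported.

Empty denominators raise an undefined-metric error rather than returning 0.

## Read-count reliability threshold

Candidates are midpoints between adjacent **distinct** sorted read counts
(ties cannot be split) with at least `min_group` samples on each side
(default 1, configurable because tiny groups give unstable tables). For
each candidate the 2×2 table below/above × discordant/concordant is tested
with the exact hypergeometric tail

    P(X ≥ a),  X ~ Hypergeom(N, K, n),

where `a` is the number of discordant samples below the cut, `K` the total
discordant count and `n` the below-cut count — one-tailed in the direction
"low-depth samples enriched for discordance", which is the failure mode of
low-coverage FFPE libraries. Tails are computed with log-gamma arithmetic
(no continuity correction); the test suite checks them against
exact-rational enumeration over all margins with N ≤ 60 at 1e-12. The
selected threshold is the candidate with the globally minimal p when that
minimum reaches `alpha` (default 0.05), ties broken toward the smaller cut;
degenerate inputs (all-concordant, all-discordant, no candidates) yield no
selection and min-p 1. The profile is a rank statistic: any strictly
increasing transform of the read counts leaves every p unchanged.

Because the minimum is taken over every candidate cut, the nominal p is
optimistic. `permutation_adjust` reports the add-one proportion of label
permutations whose scan minimum is at or below the observed one. Under
permutation the margins are fixed, so each candidate's full tail profile is
tabulated once and permuted labels only index it; B = 500–2000 permutations
run in milliseconds at cohort sizes of a few hundred. The adjusted p is a
valid (super-uniform) p-value under the exchangeable null; the suite
verifies empirical rejection ≤ 7% at the 5% level over 500 null replicates
(n = 40, B = 500).

Two reference thresholds are carried as named constants for reporting: the
assay manufacturer's 5×10⁵ reads and the 1.75×10⁵ reads derived in the
source cohort. The clinical per-sample read counts behind the latter are
not published in machine-readable form, so the package does not attempt to
re-derive that exact number from data; instead the suite demonstrates
*recoverability*: on synthetic cohorts with a steep logistic detection step
at T = 1.75×10⁵ (n = 150, slope 50 per log10 unit, saturating sensitivity,
no false positives — conditions under which discordance is exactly
"true-positive below the step"), the selected cut falls within ±0.15 of
log10 T in ≥80% of 100 seeded replicates.

## Synthetic cohorts

Per sample: log-normal depth (log10 mean/sd), true status (fusion with a
5′-partner/3′-driver pair from the panel vocabulary; exon skipping on the
lung panel; negative), per-caller detection of true events with probability
`s_max / (1 + exp(−k (log10 r − log10 T)))`, Poisson per-caller false
positives drawn from the vocabulary excluding the true pair, and — where
FISH is available — a break-apart outcome on the driver gene: translocated
for detectable fusions, negative for cryptic fusions (configurable
fraction) and for negative samples, with an unbalanced pattern at a small
rate. The reference caller emits nothing on not-evaluable samples; the
comparison callers run on everything.

Panel defaults are the study conditions: sarcoma — 31 samples, prevalence
0.45, log10 depth mean log10(894,000), sd 0.33, not-evaluable rate 3/31,
caller `s_max` 0.95/0.57/0.07 (REF/ARR/SFU) with false-positive rates
0/0.29/0.47; lung — 162 samples, positive prevalence 0.18 of which 8/29
exon skippings, depth mean log10(344,622), sd 0.45, not-evaluable rate
0.07, `s_max` 0.95/0.86/0.33 with false-positive rates 0/0.27/0.14; both
panels use detection midpoint T = 1.75×10⁵ with moderate slope 6 unless
overridden. Detection is logistic rather than a hard step: it reproduces a
smooth sensitivity decline at low depth while remaining recoverable as a
cut.

What the generator does **not** emulate: read-level data (no FASTQ/BAM),
sequence homology behind false-positive pairs (they are uniform vocabulary
draws), RNA-degradation chemistry, correlated multi-sample patients (one
sample per patient by default), or panel-specific breakpoint structure.
Passing tests on synthetic cohorts therefore demonstrate correctness of the
statistical machinery under the assumed generative model, not performance
on real FFPE libraries.

## Packaged study fixtures

The per-sample reference calls, FISH outcomes and cohort partitions of the
two-panel study cohort (31 sarcoma samples: 14 fusion-positive, 3 not
evaluable; 162 lung samples: 29 positive including 8 exon skippings, 121
negative, 12 not evaluable) are transcribed as frozen constants and written
programmatically in the package's own dialects. Facts published only as
aggregates — per-sample read counts, the identity of comparison-caller
calls, patient multiplicity — are fixed deterministic conventions chosen to
satisfy every published aggregate exactly (medians 894,000/344,622 and
range endpoints; ARR 8 confirmed + 3 different + 3 missed with 5 additional
calls, SFU 1 + 8 + 5 with 8 additional in 6 samples on the sarcoma panel;
ARR 18 + 1 + 2 with 33 additional calls in 31 samples/30 patients and SFU
7 + 3 + 11 with additional calls in 17 samples/16 patients on the lung
panel, giving negative concordance 90/121 and 104/121; exactly four
positives below 1.75×10⁵ reads). Sarcoma depths interleave positive and
negative ranks so that detection is independent of depth, matching the null
rank test in the source cohort. Re-running the fixture writer is
byte-identical.

## Numerical and degenerate-input choices

* Tail sums in plain probability space after log-gamma point masses —
  accurate to <1e-12 against exact rationals for all N ≤ 60 margins.
* Scan ties on p resolve to the smaller cut; tied read counts share a side.
* `Fraction` denominators of zero raise; rank tests with an empty group
  raise; invalid generator configs fail validation before any drawing.
* All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed reproduces cohorts, permutation p-values and on-disk files
  byte-for-byte.
* Problem sizes used by the heavier checks — 500 null replicates at n=40
  (B=500), 100 recovery replicates at n=150, 20 estimator-recovery seeds at
  n=500 — were chosen as the smallest sizes at which the binomial/3-SE
  bounds quoted above are meaningful.

## Known limitations

PPV/NPV values published for the comparison callers are reconstructible
only for the sarcoma ARR event-level construction (8/13 and 12/15); the
remaining published predictive values cannot be traced to a single
construction, so the package exposes both constructions with labels instead
of forcing agreement. Negative concordance percentages are computed on the
121-sample denominator and printed at stored precision (74.4%, 86.0%);
sources that divide by 120 will show one point higher. The threshold scan
takes its input cohort explicitly — which samples have orthogonal truth is
a study-design decision, not something the module infers.
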