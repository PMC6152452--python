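# Methods

This note documents the statistical models behind `hairsnag`, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Consensus genotyping

Noninvasive extracts are genotyped in two parallel PCR replicates. A locus
*mismatches* when two full (both-allele) calls disagree. Any mismatch demands
a second extraction genotyped twice again (replicates 3–4); a mismatch in
that round discards the whole sample. The consensus is built from the
accepted round.

A replicate in which only one allele amplified is stored as a *provisional
homozygote* with a low-confidence flag rather than discarded: a single
observed peak is exactly what allelic dropout produces, and keeping the flag
lets both consensus and identification reason about it. A provisional call is
treated as **compatible** with any call containing its allele and resolves to
the more informative call; this mirrors multi-tubes maximum-likelihood
protocols, where a partial replicate supports rather than contradicts a
heterozygote. Scoring partial replicates as mismatches would discard far more
samples than real hair-snag studies report retaining. A locus supported by
only one replicate is accepted but flagged (`confirmed_single`); a locus
failing in both replicates is missing. Samples with fewer than 8 of 10
scored loci are dropped (configurable `min_loci`). Tissue samples carry one
replicate taken at face value.

With only two replicates available and a round-1 mismatch there is no second
extraction on fixed data; such samples are reported `mismatch_unresolved`
and treated as discarded.

## Individual identification

Two consensus genotypes belong to the same animal when they match at every
compared locus, or when their allele differences — at most two in total, the
`alleleMismatch=2` convention — are each attributable to a known artifact:

- **dropout** — one genotype heterozygous, the other homozygous for the
  *smaller* allele (long fragments amplify worse), or homozygous for either
  shared allele when the homozygote carries the low-confidence flag (it is
  already a documented dropout suspect);
- **size shift** — the differing alleles are exactly one repeat unit apart
  (PCR stutter);
- **missing data** — the locus is missing in exactly one genotype (counts as
  zero allele mismatches but is recorded).

Any unexplained difference makes the pair distinct. Samples are clustered by
these pairwise verdicts; connected components are individuals. A component
containing a conflicting pair (non-transitive chaining) is flagged and split
at its weakest edge — the accepted edge with the most mismatches — until
internally consistent; silent merging is never done, matching how such cases
are curated by hand in practice. Consolidated genotypes prefer confirmed
heterozygotes over dropout-suspect homozygotes and non-missing over missing.

Sex is called from SRY: all members positive → male, all negative → female;
with mixed evidence a positive majority is called male (SRY false negatives
in degraded hair are expected) while a positive among a majority of
negatives is reported as a conflict. Individuals whose consolidated genotype
misses more than one locus are excluded from the diversity and structure
analyses (configurable `max_missing_loci`, default 1).

## Per-locus statistics

- **H_E** uses the small-sample correction (2n/(2n−1))(1 − Σp_i²); the plain
  gene diversity is exposed separately.
- **Hardy–Weinberg** is a Monte-Carlo exact test: the Pearson chi-square of
  genotype-class counts against expectations at the observed frequencies,
  with the null built by re-pairing the observed gene copies (default 10,000
  permutations, seeded). Asymptotic chi-square is invalid at 7–10 alleles on
  a few dozen individuals. p = (1 + #{null ≥ obs})/(B + 1), so the test is
  exact-conservative.
- **Null alleles**: the Chakraborty-type estimate r = (H_E − H_O)/(H_E + H_O)
  (negative under heterozygote excess), accompanied by a one-sided
  Monte-Carlo homozygote-excess test (simulate HWE draws at observed
  frequencies, compare homozygote counts).
- **F_IS and F_ST** are Weir–Cockerham (1984) variance-component estimators,
  summed over alleles and loci; with one population f = 1 − Σc/Σ(b+c), with
  two θ = Σa/Σ(a+b+c). F_ST significance comes from permuting individuals
  between groups (default 10,000 permutations). Monomorphic loci are
  excluded with a note.
- **Probability of identity**: the unbiased estimator (with N = gene copies)

      P_IDunb = (N³(2a₂² − a₄) − 2N²(a₃ + 2a₂) + N(9a₂ + 2) − 6)
                / ((N−1)(N−2)(N−3)),

  not testable for N ≤ 3, and P_IDsib = ¼ + ½a₂ + ½a₂² − ¼a₄. Cumulative
  values are products over loci. Note the ordering: P_IDsib bounds both
  other forms from above, while the unbiased estimator sits at or *below*
  the plug-in 2a₂² − a₄ because it removes that form's upward sampling bias;
  its correctness is pinned by a Monte-Carlo genotype-matching oracle test
  rather than by any convention about N.

## Population structure

Allele-sharing distance D = 1 − Σ_l s_l/(2L) over loci scored in both
individuals (s_l = multiset intersection of the two allele pairs); the
Kosman–Leonard dissimilarity, the mean over shared loci of 1 − s_l/2, is
algebraically identical for diploid data and both are exposed. Neighbor
joining follows Saitou–Nei with the standard Q criterion; a negative branch
length is clamped to zero and the excess transferred to its sister so the
pair's summed length is preserved. PCA operates on per-allele dosages
(0/1/2), mean-imputed at missing loci and column-centred.

Dissimilarity-versus-distance uses *all* genotyped samples, not unique
individuals, so a resampled animal appears as a zero-dissimilarity point at
whatever distance separates its capture sites. Geographic distance is
haversine on a 6,371 km sphere. The running average uses a sliding window
(default 20 km — the smoothing scale is a presentation choice, not an
estimate); association is tested by a Mantel-type Pearson correlation with
permutation of sample identities (one-sided for positive association).

The Bayesian clustering is the standard non-spatial admixture model fitted
by Gibbs sampling: cluster allele frequencies ~ Dirichlet(1), per-individual
memberships q_i ~ Dirichlet(α) with α fixed (default 1; sampling α buys
little at K ≤ 6 on tens of individuals), and per-gene-copy origins updated
from their conditional multinomial; missing copies are skipped. The
per-sweep trace records ln P(X | Z, P) — the data likelihood conditional on
the sampled origins — and K is scored by mean(lnL) − var(lnL)/2 over
post-burn-in sweeps. The conditional (rather than mixture) likelihood is
what makes this score penalize overfitted K: extra clusters thin the data
behind each frequency estimate and inflate the variance term. K = 1 reduces
to frequency sampling with all memberships 1. Default 6,000 sweeps with
2,000 burn-in mixes thoroughly at this problem size (≤ ~100 individuals,
10 loci); label switching across runs is resolved by best permutation when
comparing to an external truth.

## Sampling-success analysis

Success = a retained ≥ 8-locus consensus. The by-source table covers
noninvasively collected hair only; the by-year table covers all hair
(tissue excluded). Pearson chi-square without continuity correction —
required for consistency with how such 2×2 pooled comparisons are
conventionally reported; expected counts below 5 raise a warning, not an
error, because pooled field tables routinely have sparse columns.

## Synthetic data generator

The generator emulates a two-province hair-snag study. Ancestral allele
frequencies are Dirichlet(1) per locus (7–10 alleles, dinucleotide grid);
province frequencies follow the Balding–Nichols construction
(Dirichlet(p(1−F)/F)) with default target F_ST = 0.005 — negligible
differentiation, as appropriate for connected mountain subpopulations.
Genotypes are Hardy–Weinberg draws, or identical-by-descent with probability
`inbreeding_f`. Detection is male-biased (default 83.3% male among sampled
animals, matching rub-object behaviour).

The error process per replicate and locus: whole-locus amplification failure
at a source-specific rate; stutter shifting an allele ±1 repeat unit
(default 0.005/allele); a false allele substituted from the locus ladder
(default 0.01/locus); and length-biased dropout — the larger allele of a
heterozygote drops at `dropout_rate` (default 0.05), the smaller at one
third of that. One surviving allele yields a provisional homozygote; none
yields a missing locus. SRY flags equal true sex except for a 1%
misamplification rate. When round 1 mismatches, the generator emulates the
lab loop and produces replicates 3–4.

Per-source failure rates are derived by inverting the published per-source
success rates: with per-locus consensus-missingness m = q², q solves
P(Binom(10, m) ≤ 2) = success rate (poles 26.39%, rubbing trees 54.72%,
barbed wire 83.33%, hair traps 42.86%). The study-like dataset reproduces
the exact accounting: 154 samples = 7 tissue + 3 invasive capture hairs +
144 noninvasive hairs (72/53/12/7 by source), 20 hairs from the smaller
province collected in 2012 only, yearly totals matching the published
distribution, and province centres ~160 km apart.

**What the generator does not emulate.** Locus failures are independent
across loci given the source, whereas real samples have a shared DNA-quality
factor that concentrates missingness in bad samples; synthetic consensus
genotypes therefore spread missing loci more evenly, and the ≤ 1-missing-locus
analysis filter removes proportionally more synthetic individuals than it
removed real ones. There is no home-range movement model (coordinates are
Gaussian jitter around a per-animal home), no pedigree structure (so
P_IDsib is exercised only through frequencies, not actual sibs), and no
allele-size-dependent mutation model. Passing tests therefore validate the
estimators and the pipeline logic under the stated generative assumptions,
not the field realism of any particular dataset.

## Numerical conventions and degenerate inputs

Missing alleles are `None` internally; CSV sentinels are configurable
(default 0 / blank / NA). A provisional homozygote is serialized as its
actual observation — one allele and one blank — so its flag survives file
round trips. All permutation p-values use the add-one rule and are therefore
never zero. Monomorphic loci return a NOT_TESTABLE sentinel from HWE and are
excluded from F-statistics. Distance matrices assert symmetry and a zero
diagonal on construction; pairs sharing no scored locus are NaN and named in
the result. Ties in NJ's Q matrix resolve by lowest index, making trees
deterministic. Every stochastic routine takes an explicit seed; a
`SimulationConfig` with the same seed reproduces its dataset bit-for-bit.

## Problem sizes used in the validation suite

Parameter-recovery and calibration tests run at sizes where the checked
quantity is decisive yet quick: F_IS recovery at n = 500 individuals,
θ recovery at 50+50, HWE type-I calibration over 1,000 replicates of n = 50
with 999 permutations, the P_ID oracle with 10⁶ genotype pairs and 3,000
finite resamples, and admixture assignment at 30+30 individuals with
2,000 sweeps. The full suite completes in well under a minute on one core.
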