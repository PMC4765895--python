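# Methods

## Pipeline model and assumptions

The pipeline treats three inputs as given: (i) case/control gene-expression
matrices with binary phenotype labels, (ii) a compendium of drug-treatment
instances, each a full rank permutation of a shared gene universe, and (iii) a
metabolic reaction table (one catalyzing enzyme gene, ≥1 substrate, ≥1 product
per reaction) plus per-drug target/compound annotations.  It assumes the
datasets share (most of) one gene universe, that reversal of a disease
signature in treated cell lines is evidence of potential therapeutic effect,
and that co-expression module structure plus metabolic-link enrichment
identifies metabolically central, disease-specific enzymes.

### Differential expression

Moderated two-sample t-test with method-of-moments empirical-Bayes shrinkage:
the pooled per-gene variance is shrunk toward the across-gene mean variance
with prior weight `d0` (default 4), and the statistic is referred to a t
distribution with `n1 + n2 - 2 + d0` degrees of freedom.  With `d0 = 0` this
reduces exactly to the ordinary pooled t-test (a tested limit case).  The
shrinkage weight matters at small n; 4 pseudo-degrees is a deliberately mild
default.  All datasets are analyzed unpaired — matched-pair designs exist in
real data of this kind, but a paired analysis is not implemented.
Normalisation applies `log2(v + 1)` (not `log2 v`) when the overall median
exceeds 16, so zeros are tolerated; "too many nulls" is operationalized as
missing fraction > 0.2, and remaining missing entries are imputed with the
gene's per-class mean.  Inter-dataset concordance is the Pearson correlation
of per-gene mean expression over common genes (the natural reading of
"expression profile of the common genes"; medians or concatenated profiles
are plausible alternatives).

### Connectivity

Rank orientation is a convention the underlying data sources state
inconsistently; this package fixes **rank 1 = most drug-up-regulated** and
provides `reverse_profile` to flip a profile wholesale.  The signed KS
statistic follows the classic two-tag enrichment formulation (`a`/`b` max
expressions); the combined score `ks_up - ks_down` is zeroed when both tags
are enriched on the same side.  The "KS test" p-value is realized as a
permutation test on the signed combined score: random gene sets of the
observed sizes, drawn without replacement from the profile universe, with
`p = (1 + #{null <= obs}) / (1 + n_perm)` (one-sided for reversal, never 0).
An asymptotic two-sample KS alternative was considered and rejected: the
permutation null matches the statistic actually screened and makes the
one-sided reading unambiguous.

Within a screen, one null sample is shared by all instances.  This is exact,
not an approximation: a random gene set's positions in *any* permutation are a
uniformly random rank subset, so the null law depends only on (|up|, |down|,
n).  Sharing makes p-values monotone in the observed score by construction
and cuts the screen cost by a factor of the instance count.  Signature genes
missing from the profile universe are dropped with a warning by default
(platform mismatch is expected in real data); an error mode is available.

A caveat documented here because it affects calibration checks: the zeroing
rule gives the null score distribution an atom at 0 (mass ≈ 0.5 for balanced
tags).  Permutation p-values are therefore exactly calibrated in the
significant (continuous, negative-score) tail and conservative elsewhere —
they are *not* globally uniform, and no implementation of this score could
make them so.  The acceptance tests assert tail calibration and global
super-uniformity accordingly.

### Key-enzyme prediction

The co-expression network joins gene pairs with |Pearson r| ≥ `min_abs_pcc`
(default 0.7) across all samples; constant genes carry no edges.  Modules are
Louvain communities (seeded, unweighted) on the connected subgraph — greedy
modularity maximization with local-move refinement — with isolated genes kept
as singleton modules and module ids assigned deterministically by size then
lexicographic member.  Any modularity-based partitioner would preserve the
pipeline's semantics; Louvain was chosen because it is seeded, fast and
standard.

Cancer-specificity of a module is the ROC AUC of its per-sample median
expression, computed by tie-aware pair counting and **oriented** as
`max(AUC, 1 - AUC)`: a consistently down-regulated module is as
disease-specific as an up-regulated one, and the published procedure does not
state an orientation.  The importance score is this package's concrete
instantiation of "cancer-specificity × within-module metabolic-link
enrichment" (the original combination rule lives in a prior publication and is
only sketched in the source this design follows):

    score(g) = AUC(m(g)) × (−log10 P[X ≥ d_in]),  X ~ Hypergeom(M, K_m, d_tot)

with M the number of scored enzymes, K_m the module's enzyme count (including
g, matching the worked convention in the design examples), d_tot the enzyme's
links among scored enzymes and d_in those inside its own module.  The tail
probability is floored at 1e-300 before the log.  Key enzymes are those
**strictly** above the median score (ties at the median are excluded; with
mostly-zero scores this means "any positive evidence").  The currency-compound
exclusion list for link building is configurable and empty by default.

### Selection

"More than half" of a drug's instances is strict (2 of 4 does not qualify);
"at least two datasets" is ≥.  The overlap randomization draws size-matched
drug sets per dataset uniformly from the screened-drug universe (conditioning
on per-drug instance counts was considered and omitted — the statistic
compares set overlaps, not per-drug significance).  Candidate rationale
categories are mutually exclusive with target-route priority.  Fisher
enrichment is one-sided toward over-representation, BH-adjusted at fdr < 0.1.

### Assay

Inhibition is computed per replicate against the mean vehicle OD and the
blank, then averaged per concentration with the sample SD (ddof 1) as the
spread — this ordering yields the replicate error bars directly.  No IC50 or
4PL fitting is attempted.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular platform:

* **Expression** — latent-factor modules: gene g in module m has expression
  `mean_g + loading_g · f_m(s) + noise`, `loading ~ U(0.5, 1.5)` (shared
  across datasets), `f_m ~ N(0,1)` in normal samples and `N(δ,1)` in cancer
  samples of cancer-specific modules (δ = 2 by default, 2 of 4 modules
  cancer-specific).  Baseline means `~ N(8, 1.5²)` are drawn per dataset.
  Planted DE genes are sampled *outside* the modules (so DE truth and module
  truth stay separable) and shifted ±Δ (default 3) in cancer samples; the
  same DE genes are planted in every dataset, which is what makes a
  signature-reversing drug consistently detectable across datasets.  Missing
  entries are MCAR at rate 0.02.
* **Rank profiles** — per-gene scores `ε ~ N(0,1)`, minus `β·s_g` (β = 2) for
  reverser drugs acting on the *planted* signature; ranks by descending
  score.  Acting additively on scores (rather than swapping ranks) gives a
  tunable effect size.  Downstream screens use the *estimated* signatures, so
  recovery tests exercise the full estimation path.
* **Metabolic model** — each planted key enzyme catalyzes a reaction whose
  product is consumed by `partners_per_key` (default 4) co-module partner
  enzymes: keys are within-module product→substrate hubs.  Keys and partners
  are drawn from the upper-loading half of their cancer module, because the
  planted truth is "a strongly co-expressed, metabolically central enzyme" —
  a gene too weakly loaded to join its module's detected co-expression
  component would not be a key enzyme under the model being emulated.
  Background enzymes live outside the cancer modules with fresh-compound
  reactions plus sparse cross links (`n_reactions` is the background budget).
* **Drug annotations** — planted candidates (default 6, alternating target /
  metabolite route) are reversers wired to planted keys; all other drugs get
  1–3 non-enzyme targets and compounds absent from every reaction, so they
  cannot be selected.

Every stage derives its RNG stream from `[stage_tag, seed]`, so regeneration
is deterministic and stages are independently reproducible.

**What the generator does not emulate** (and hence what passing tests do not
show about real data): probe-level microarray noise, batch effects,
platform-dependent gene universes, matched-pair correlation, realistic
metabolic network topology (hub degree distributions, currency metabolites),
drugs with many targets, or correlated baseline means across datasets — the
per-dataset redrawn baselines mean inter-dataset mean-expression correlation
in synthetic data is near zero, far below what real replicated tissue
datasets show; only its sign is meaningful here.

## Default conditions and problem sizes

The default `SimulationConfig` is the study condition exercised throughout:
3 datasets × 2,000 genes × (30 normal + 30 cancer), 4 modules of 30–60 genes,
δ = 2, σ = 0.5, 5% DE genes at Δ = 3, 200 drugs × 5 instances with 10
reversers at β = 2, 100 enzymes with 10 planted keys, 6 planted candidates,
2% missingness.  δ, Δ and β have no real-data estimates to anchor them; they
are operational choices picked once to represent a clearly-powered study, and
the null-calibration tests set all three to zero.  Unit tests use a reduced
configuration (400 genes, 2 datasets, 40 drugs) that preserves structure
rather than statistical power; the planted-recovery acceptance test runs the
full default conditions over 10 seeds, and the null-calibration tests use 50
replicates of a 300-gene null configuration.

## Numerical choices and degenerate inputs

* BH adjustment via the standard step-up implementation; inputs outside
  [0, 1] are rejected, empty input returns empty.
* Permutation p-values carry the +1 correction and are never 0; `n_perm <
  100` warns, ≤ 0 errors.
* KS positions must be strictly increasing integers in 1..n; empty sets
  error.  Score combination treats an exact 0 in either tag as "differing in
  sign".
* AUC ties count ½ via midranks; a module absent from the dataset errors; a
  constant score vector gives 0.5.
* Zero-variance genes: excluded from network edges with a warning; in DE,
  zero pooled variance with zero change reports p = 1 (and is impossible with
  d0 > 0 unless all genes are constant).
* Louvain determinism: graph built with sorted nodes/edges, fixed seed,
  deterministic module labelling.
* `overlap_randomization` sorts the universe before sampling so results
  depend only on set contents, not iteration order.

## Known limitations

* The importance-score combination rule is an approximation of a procedure
  whose exact form is published elsewhere; only its two ingredients
  (module-AUC and within-module link enrichment) are specified here.
* Real rank compendia scale scores within result sets and weight instance
  quality; neither is modelled.
* The unpaired DE analysis discards pairing information real datasets of this
  design would have.
* Counts reported by the original study (e.g. numbers of screened/selected
  drugs and enzymes) depend on external resources and are intentionally not
  reproduced; the pipeline's correctness is established by planted-truth
  recovery, oracle equivalence and null calibration instead.
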