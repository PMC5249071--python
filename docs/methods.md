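# Methods

## Model

The package treats SNP genotyping as a diagnostic test applied on top of a
clinical risk model. A woman's prior is her 5-year absolute risk of
invasive breast cancer from the clinical model; the test result is her
multi-locus genotype; the update is Bayes' rule on the odds scale with the
genotype likelihood ratio.

Per locus, with risk-allele frequency `p`, per-allele odds ratio `γ` and
prevalence `K`:

- population genotype probabilities are Hardy-Weinberg,
  `((1−p)², 2p(1−p), p²)` over 0/1/2 risk-allele copies;
- per-genotype relative risks are multiplicative, `(1, γ, γ²)` — the
  standard polygenic-score convention, consistent with the product-of-LRs
  construction; no dominance terms;
- case probabilities reweight the population triple by the relative risks
  and renormalise; control probabilities are the complementary mixture
  component, so `K·P(g|D+) + (1−K)·P(g|D−) = P(g)` holds to machine
  precision by construction.

The case expression is the low-prevalence approximation of the
retrospective genotype distribution, and `γ ≈ relative risk` likewise
requires rare disease, so the model refuses `K > 0.10`. `K` defaults to
0.05; the headline quantities are insensitive across `K ∈ [0.01, 0.10]`
because `K` enters only the small case/control contrast of each locus.

Loci are assumed independent (linkage equilibrium) and interaction-free;
the panel LR is the product of per-locus LRs, accumulated as a sum of logs
and exponentiated once (validated against the naive product to 1e-9
relative on 70-locus panels). Panels must be LD-pruned upstream; the
package performs no LD checks.

### Assumptions worth stating plainly

- Control-expected LR is exactly 1 per locus (algebraic identity), so the
  posterior update conserves population risk to first order in `K`.
- Genotypes are independent of every clinical risk factor except family
  history. The priors already embed family history, which is why that one
  factor needs explicit treatment (below).
- ORs are treated as per-allele relative risks; at `K ≤ 0.10` the
  distinction is below the Monte-Carlo noise of everything reported.

## Family history

Risk alleles are enriched among women with an affected first-degree
relative, and the clinical prior already contains a familial relative risk
`RR_FH`; applying the full LR to such a prior double-counts the shared
part. Two constructions handle this:

1. **FH-conditioned genotypes.** The affected relative is modelled as a
   case; the proband shares half her genome, so her risk-allele frequency
   is `p_FH = p + (p_case − p)/2` with
   `p_case = P(g1|D+)/2 + P(g2|D+)`, and her genotypes are Hardy-Weinberg
   at `p_FH`. This is the simplest single-affected-relative kinship-½
   model; multiple affected relatives or relative's age at onset are not
   modelled.
2. **Attenuation of the familial prior.** The proportion of familial risk
   carried by the panel is `π̂ = log E[LR | FH+] / log RR_FH`, clamped to
   [0, 1], where `E[LR | FH+]` is the product over loci of the mean LR
   under the FH-conditioned triples. The posterior for an FH+ woman
   divides her prior odds by `RR_FH^π̂` before applying her LR. Defining
   `π̂` through the *mean LR* (not the mean log-LR) makes the construction
   self-consistent: averaged over FH-conditioned genotypes the deflation
   exactly cancels the expected LR uplift, so the population of FH+ women
   keeps its familial prior on the odds scale. (On the probability scale a
   small Jensen gap of order the LR variance times the prior remains,
   ~1% of the prior for the reference panel.)

`RR_FH` defaults to 2.0, the standard first-degree-relative figure, and
the reference panel carries `π̂ ≈ 0.19` of it. The family-history rate
defaults to 0.114, the first-degree-family-history prevalence of the BCSC
screening population. The FH flag is sampled independently of the prior;
in reality FH+ women concentrate in the high-prior bins, so stratified
FH analyses from this simulation are qualitative. Population-level
quantities are unaffected (the flag only switches which genotype triples
and which posterior formula apply).

## Prior-risk distribution and cohort synthesis

The screening population enters as binned 5-year-risk masses. The built-in
coarse table is the published 7-category distribution of BCSC 5-year risk
among 796,294 non-Hispanic White screening participants ages 35–69
(categories <1.0%, 1.0–1.4%, …, >4.0%; half-open `[lower, upper)`
convention). The printed percentages sum to 100.1; they are normalised
proportionally, treating the excess as rounding slack, not signal.

Within-bin placement is uniform — the maximum-entropy choice; midpoints
would stack mass exactly at decision thresholds and bias crossing rates.
The open top bin is drawn from the conditional tail of a lognormal fitted
to all bin masses, capped at a 5-year risk of 0.30.

The lognormal fit minimises the unweighted sum of squared differences
between model and observed bin masses over (μ, σ), from four
moment-informed starts with Nelder-Mead. On the coarse 7-bin table the
best two-parameter lognormal is an imperfect summary: worst bin error
1.63 percentage points and tail mass above 3% high by 1.3 points (these
are the global-optimum residuals, frozen into the tests). This matters
only for the top-bin tail shape — cohort sampling takes the bin masses
themselves as exact — and a parameter-recovery test confirms the fitter
recovers truly lognormal marginals to well under 5%.

The real analysis this emulates assigned each woman her individually
computed prior; only bin masses are public, so the within-bin uniform
assumption is irreducible here. Passing tests therefore demonstrate the
machinery and the population-level accounting, not the exact
threshold-crossing rates of any particular empirical prior distribution.

## Reference panel

No real locus list is bundled; the package ships a synthetic stand-in
(labelled as such) for a ~70-SNP breast-cancer GWAS panel: 70 independent
loci with `p ~ U(0.05, 0.5)` and
`OR ~ U(1.03, 1.15)`. The OR range was calibrated once against the
closed-form discrimination target: the panel log-LR variance is
`σ² = Σ 2p(1−p)(ln γ)²`, giving `AUC ≈ Φ(σ/√2)`, and the chosen ranges put
the expected σ near 0.46, i.e. AUC ≈ 0.63 — the figure empirical
~70-SNP panels achieve. The naive GWAS-wide OR range (up to ~1.26)
overshoots that variance. For ≥95% of generator seeds the closed-form AUC
lands in [0.60, 0.65].

## Discrimination

Cases and controls (default 5000 + 5000, mirroring the published internal
check) are simulated from their respective genotype triples and scored by
the panel log LR. AUC uses the tie-corrected Mann-Whitney estimator
(exact pair counting, no trapezoid binning): 70-locus scores are
effectively continuous, but single-locus score sets are three-valued and
need the tie correction. The closed-form `Φ(σ/√2)` value is the analytic
oracle; simulation agrees within 0.015 at these arm sizes.

## Reclassification accounting

The treatment threshold is 3% 5-year risk, applied as `posterior ≥ 0.03`
(the "at or above" reading of the guideline). A testing strategy is a
half-open band of *prior* risk `[lower, upper)`: women in the band are
genotyped and acted on by posterior; everyone else keeps the prior.
Crossings of the threshold are tallied in both directions as fractions of
the whole population, and a strategy's benefit fraction is its total
crossings divided by the test-everyone total *on the same cohort* — a
paired comparison, so Monte-Carlo noise cancels between strategies and the
benefit curve of nested bands is monotone by construction. Report tables
round percentages to one decimal; machine-readable outputs keep full
precision.

Default strategy ladder: the 2.5–3.9% band, then nested open bands ≥2.5%,
≥2%, ≥1.5%, ≥1%, and test-everyone.

## Determinism and problem sizes

Every stochastic stage takes a `numpy` `Generator` or an integer seed; the
model's `fit` spawns two independent child streams (cohort synthesis;
case/control simulation) from one root `SeedSequence`, and the pipeline
derives the panel-generation stream from the same root, so stages are
individually reproducible and identical configurations give byte-identical
outputs. Default sizes — 200,000-woman cohort, 5000+5000 AUC arms — hold
the Monte-Carlo standard error of every reported percentage near or below
0.1 points while keeping a full run in the tens of seconds; the test suite
uses these sizes for headline checks and smaller cohorts for structural
ones.

## Known limitations

- Single-affected-relative, kinship-½ family-history model; no
  relative-age or multiple-relative structure.
- FH flag independent of the prior within the simulation (see above).
- No ER-subtype-specific effects, no SNP×SNP interactions, no LD handling,
  no cost-effectiveness or harms weighting.
- The clinical risk model that produces priors is an input, not
  implemented; subgroup-stratified prior tables are accepted as input but
  ship with no built-in data beyond the overall coarse marginals.
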