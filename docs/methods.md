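# Methods

## Model

`gmtrial` works with the balanced multi-site randomised-complete-block
mixed model for log-scale responses

    Y_ijk = μ + S_i + B_ij + G_k + (SG)_ik + e_ijk,
    i = 1..s sites, j = 1..b blocks within site, k = 1..g genotypes,

where S, B, (SG) and e are independent zero-mean normal effects with
variances σ²_site, σ²_block, σ²_SxG and σ²_e.  The genotype roster
always contains exactly one GMO, exactly one comparator and r ≥ 1
reference varieties; the genotype term is partitioned into a fixed
three-level *group* factor (GMO / comparator / reference-as-a-whole) and
a random varieties-within-reference term with variance σ²_genotype —
the reference varieties are modelled as a sample from the population of
commercial non-GM varieties, so σ²_genotype (written V_g in the
equivalence context) measures that population's natural variation.

The site-by-genotype interaction is partitioned to match the genotype
partition, into three orthogonal strata:

| stratum                  | meaning                                              | df         |
|--------------------------|------------------------------------------------------|------------|
| site × test-entry        | GMO-vs-comparator contrast changing across sites     | s − 1      |
| site × reference         | reference varieties re-ranking across sites          | (s−1)(r−1) |
| site × group remainder   | test-pair-vs-reference-group contrast across sites   | s − 1      |

The simulator accepts either one pooled interaction variance or separate
test-entry / reference components (interaction with site may genuinely
differ between the test entries and the reference population); the two
parameterisations are mutually exclusive.  Normality of all random
effects is an assumption of the framework — responses are taken to be
already log-transformed, and the package performs no transformation.

## Balanced ANOVA, EMS and moment estimation

Because every design is complete and balanced, all strata are orthogonal
and the decomposition is exact arithmetic on marginal means: no
iterative fitting anywhere.  Contrast strata use the standard quadratic
form b·Σ_i (L_i − L̄)²/c'c; the residual is computed directly from the
within-site two-way fit (plot minus block mean minus cell mean plus site
mean), so the SS-additivity check in the tests is a genuine invariant
rather than a bookkeeping identity.

Expected mean squares (zero fixed offsets, random reference effects):

    residual                   σ²_e
    site × test-entry          σ²_e + b σ²_t
    site × reference           σ²_e + b σ²_r
    site × group remainder     σ²_e + b (σ²_t/2 + σ²_r/r) / (1/2 + 1/r)
    varieties-within-reference σ²_e + b σ²_r + s b σ²_genotype
    blocks-within-site         σ²_e + g σ²_block
    site                       σ²_e + b(2σ²_t + rσ²_r)/g + g σ²_block + b g σ²_site
    genotype group             mean of its two 1-df contrast EMS (the
                               remainder-type contrast also carries
                               s·b·(σ²_genotype/r)/(1/2 + 1/r))

All eight were verified against Monte-Carlo mean squares by simulation
(the test suite repeats this at 20,000 replicates).  Method-of-moments
estimation inverts these equations bottom-up; negative solutions are
truncated at zero and flagged, with the untruncated values retained for
unbiasedness diagnostics.  Unbalanced or incomplete datasets are
rejected: the closed forms do not apply, and REML fitting of unbalanced
layouts is deliberately out of scope for this version.

## The two difference tests

Both tests use the raw mean difference d̂ = ȳ_GMO − ȳ_comparator.

**Naive** (no-interaction model): SE² = 2·MSE_pooled/(s·b), where
MSE_pooled pools all three interaction strata with plot error;
df = (s−1)(g−1) + s(b−1)(g−1).  In the balanced case this closed form is
exactly the GLS/OLS contrast from the no-interaction fixed-effects fit
(the test suite checks it against a statsmodels OLS `t_test`), so no
mixed-model iteration is needed.  Its level is exact only when every
interaction variance is zero.

**Interaction-aware**: SE² = 2·MS_SxT/(s·b) on (s−1)(t−1) = s − 1 df
(t = 2 test entries).  Writing d_i for the per-site GMO-minus-comparator
mean, MS_SxT = (b/2)Σ(d_i − d̄)²/(s−1), so the statistic is identically
the one-sample t-test on the d_i: exactly t_{s−1} under the null for
*any* interaction variance.  This is why the corrected test holds its
nominal level at every interaction ratio while the naive test does not.
When MS_SxT < MS_residual the interaction mean square is still used
unchanged (no pooling): a deliberate, documented choice that keeps the
error term's meaning fixed; pooling strategies can be layered on by the
caller.

The G×E check is F = MS_SxT/MS_residual on (s−1, s(b−1)(g−1)) df.  Its
numerator can be computed under either a random-site labeling (closed
form) or a fixed-site labeling (statsmodels OLS refit of the test-entry
subset); balanced orthogonality makes the two routes numerically
identical, which the tests assert at 1e-12 relative tolerance.

## Equivalence testing

The baseline for equivalence is the reference *population*, not a fixed
treatment, so the between-variety variance enters the limits:

    limits = ± t(1−α, r−1) · sqrt(V̂_g + Var̂(D)),
    D = ȳ_GMO − ȳ_reference,

with V̂_g the moment estimate and Var̂(D) = MSE_pooled/(s·b) +
MS_ref/(s·b·r) (site and block effects cancel from the contrast; the
identity Var(ȳ_ref) = MS_ref/(s·b·r) puts the variety count, not the
plot count, under V_g).  The verdict uses TOST geometry on the (1−2α)
CI for D: EQUIVALENT inside, NOT_EQUIVALENT entirely outside one limit,
INCONCLUSIVE otherwise.  α defaults to 0.05, independent of the
difference test's 0.1.

The exact published limit construction for this setting lives in a
companion methodology whose formulas are not reproduced here; the
LSD-style formula above implements the stated principle (V_g explicitly
in the baseline) and is isolated in `equivalence_limits` so it can be
swapped without touching callers.  Two modes address the open question
of whether limits should reflect references performing differently
across sites: the default uses the no-interaction decomposition, and an
*interaction-inflated* mode adds σ̂²_SxRef to the baseline and uses
MS_SxT for the GMO arm; `analyze` reports both.

When the user supplies fixed limits, the reference set is treated as a
fixed treatment: V_g drops out of the contrast SE (pooled error on
pooled df instead), which makes the verdict invariant to the spread of
the reference varieties given their mean — the property that
distinguishes pre-specified from study-specific limits.  Study-specific
limits, by contrast, move with whichever reference varieties a study
happened to include; the test suite demonstrates the resulting
verdict-flipping across simulated replicates of the same GMO.

## Simulation and the Monte-Carlo engine

The generator draws effects in a fixed order (genotype, site, block,
interaction, residual) from `numpy` Generator streams; replicate r of a
batch uses `default_rng([seed, r])`, so single replicates are
reproducible in isolation and batches parallelise.  Reference-variety
effects are redrawn for every dataset — each simulated trial samples its
own references from the population, which is exactly what makes
study-specific equivalence limits fluctuate.

The power engine sweeps μ_GMO ∈ {0, 0.02, 0.05, 0.07, 0.10, 0.12, 0.15,
0.17, 0.20, 0.22, 0.25} (the alternating +0.02/+0.03 spacing) crossed
with interaction-to-genotype variance ratios {0, 0.5, 1}, 1000
replicates per cell by default, rejecting when p < α, and reports
binomial standard errors sqrt(p̂(1−p̂)/n) without continuity correction.
Each cell gets an independent child seed (below 2³¹) derived via
`SeedSequence`, recorded in the output table.

### Default study conditions

The shipped defaults are s = 4 sites, b = 4 blocks, r = 6 reference
varieties and, on the log scale, σ²_site = 0.04, σ²_block = 0.005,
σ²_genotype = 0.02, σ²_e = 0.01.  The four-site, two-test-entry layout
(hence 3 interaction df) is the canonical configuration for this
methodology; block and reference counts and the variance components are
realistic stand-ins for compositional endpoints, chosen so that
site-to-site variation dominates, plot error is comparatively small, and
reference varieties differ by a few percent — and they are deliberately
user-overridable (every default appears literally in
`src/gmtrial/data/default_config.toml`, which also carries a named
`companion-paper` profile slot to be filled with an external protocol's
exact components when reproducing its printed rejection rates).  Under
these defaults the naive test's null rejection rate at nominal 0.1 rises
to roughly 0.3 at ratio 0.5 and 0.4 at ratio 1 — the same order as the
published critiques of the no-interaction analysis — but the exact
values depend on the variance components, which is why the acceptance
checks assert the ordering and material inflation rather than specific
rates.

### What the simulator does not emulate

Real compositional data bring skewness and measurement-floor censoring,
correlated multi-analyte panels, incomplete designs with different
reference sets per site, and multi-year structure.  None of these are
generated, so passing tests establish the arithmetic and the
distributional claims *under the model*, not robustness to departures
from it.

## Numerical choices and problem sizes

Closed forms throughout mean no tolerances beyond floating point; SS
additivity is asserted at 1e-9 relative, route-equivalences at 1e-10 to
1e-12.  Monte-Carlo unit tests use 300–5000 replicates with 2–3
standard-error bands and fixed seeds; the end-to-end suite uses 1000
replicates per rejection-rate condition (matching the convention for
such studies) and 20,000 for the EMS identities.  A full
11 × 3 × 1000-cell power sweep takes on the order of a minute on a
single core.

## Known limitations

Only complete balanced designs; no REML, Satterthwaite or
Kenward–Roger machinery; single endpoint (no multiplicity across
analytes); no per-site ("individual") difference or equivalence
verdicts — how to interpret equivalence in the presence of interaction
site-by-site remains an open methodological question, and this package
confines itself to exposing the two limit modes side by side.
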