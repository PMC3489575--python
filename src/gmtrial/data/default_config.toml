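# Default gmtrial configuration.
#
# Design dimensions and test sizes follow the package defaults (4 sites,
# 4 blocks per site, 6 reference varieties; difference test at alpha =
# 0.1, equivalence at alpha = 0.05).  The variance components are
# realistic log-scale stand-ins for compositional endpoints and are
# meant to be overridden with study-specific values.

[design]
n_sites = 4
n_blocks = 4
n_reference = 6

[means]
mu_overall = 1.0
mu_gmo_offset = 0.0
mu_comparator_offset = 0.0

[varcomps]
sigma2_site = 0.04
sigma2_block = 0.005
sigma2_genotype = 0.02
sigma2_interaction = 0.0
sigma2_residual = 0.01

[simulation]
seed = 0

[difference]
alpha = 0.1

[equivalence]
alpha = 0.05

[power]
# mu_GMO grid with the alternating +0.02/+0.03 spacing
mu_gmo_values = [0.0, 0.02, 0.05, 0.07, 0.10, 0.12, 0.15, 0.17, 0.20, 0.22, 0.25]
# site-x-genotype interaction variance as a multiple of sigma2_genotype
interaction_ratios = [0.0, 0.5, 1.0]
n_reps = 1000
alpha = 0.1
test_choice = "naive"

# "companion-paper" profile: fill in the variance components of the
# methodology under scrutiny to reproduce its published rejection rates
# exactly; left equal to the stand-ins until those values are sourced.
[profiles.companion-paper.varcomps]
sigma2_site = 0.04
sigma2_block = 0.005
sigma2_genotype = 0.02
sigma2_interaction = 0.0
sigma2_residual = 0.01
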