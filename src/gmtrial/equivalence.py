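"""Equivalence testing of the GMO against the reference population.

The reference varieties in the trial are treated as a random sample
from the population of commercial non-GM varieties with a history of
safe use, so the baseline for equivalence is not a single treatment mean
but a population: its between-variety variance V_g enters the
equivalence limits explicitly.  The limits here are an
LSD-style construction

    limits = +/- t(1 - alpha, r - 1) * sqrt(V_g_hat + Var_hat(D))

centred on zero, where D is the GMO-minus-reference-population-mean
contrast and r the number of reference varieties; the verdict follows
TOST geometry on the (1 - 2*alpha) confidence interval for D.

Because the limits are rebuilt from whichever reference varieties a
study happened to include, they are study-specific: two trials of the
same GMO can reach different verdicts purely through the luck of the
reference draw.  ``equivalence_test`` accepts ``fixed_limits`` to
explore the pre-specified-limits alternative, and an
``interaction_inflated`` mode that adds the site-by-reference
interaction variance to the baseline (should limits reflect that
reference varieties perform differently at different sites?).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .anova import AnovaDecomposition, decompose, estimate_varcomps
from .dataset import TrialDataset
from .design import DesignError, GenotypeGroup
from .difference import mean_difference


class Verdict(enum.Enum):
    EQUIVALENT = "equivalent"
    NOT_EQUIVALENT = "not_equivalent"
    INCONCLUSIVE = "inconclusive"


class LimitsSource(enum.Enum):
    STUDY_SPECIFIC = "study_specific"
    USER_FIXED = "user_fixed"


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceVariation:
    """Reference-population summary extracted from one trial."""

    mean: float
    v_g: float
    se_mean: float
    df: int  # genotype-within-reference stratum df, r - 1


@dataclass(frozen=True)
class EquivalenceResult:
    estimate: float  # GMO mean minus reference-population mean estimate
    confidence_interval: tuple[float, float]  # level 1 - 2*alpha
    limits: tuple[float, float]
    v_g_estimate: float
    verdict: Verdict
    limits_source: LimitsSource
    alpha: float
    interaction_inflated: bool = False

    def __str__(self) -> str:
        lo, hi = self.confidence_interval
        llo, lhi = self.limits
        return (
            f"equivalence test ({self.limits_source.value}"
            f"{', interaction-inflated' if self.interaction_inflated else ''}): "
            f"estimate={self.estimate:.6g} "
            f"{100 * (1 - 2 * self.alpha):g}% CI [{lo:.6g}, {hi:.6g}] "
            f"limits [{llo:.6g}, {lhi:.6g}] V_g={self.v_g_estimate:.6g} "
            f"-> {self.verdict.value}"
        )


def estimate_reference_variation(
    data: TrialDataset, decomp: AnovaDecomposition | None = None
) -> ReferenceVariation:
    """Reference mean, between-variety variance V_g, and the SE of the mean.

    V_g comes from the method-of-moments inversion of the
    genotype-within-reference expected mean square.  The SE of the
    reference mean as an estimate of the *population* mean (net of the
    site and block effects shared with the test entries) has the closed
    form sqrt(MS_ref / (s*b*r)), which puts the variety count — not the
    plot count — in the V_g denominator.
    """
    d = data.design
    if d.n_reference < 2:
        raise EstimationError(
            "cannot estimate natural variation from fewer than 2 reference varieties"
        )
    if decomp is None:
        decomp = decompose(data)
    s, b, r = d.n_sites, d.n_blocks_per_site, d.n_reference
    ref_mask = data.frame["group"] == GenotypeGroup.REFERENCE.value
    ref_mean = float(data.frame.loc[ref_mask, "response"].mean())
    vc = estimate_varcomps(decomp, d)
    ms_ref = decomp.ms("genotype_within_reference")
    se = float(np.sqrt(max(ms_ref, 0.0) / (s * b * r)))
    return ReferenceVariation(
        mean=ref_mean, v_g=float(vc["sigma2_genotype"]), se_mean=se, df=r - 1
    )


def _contrast_variance(
    decomp: AnovaDecomposition, interaction_inflated: bool
) -> float:
    """Estimated variance of the GMO-minus-reference-mean contrast.

    Site and block effects cancel from the contrast.  The GMO arm uses
    the pooled no-interaction error by default, or the site-by-test-entry
    mean square in interaction-inflated mode; the reference arm is
    MS_ref / (s*b*r) in both.
    """
    d = decomp.design
    s, b, r = d.n_sites, d.n_blocks_per_site, d.n_reference
    if interaction_inflated:
        gmo_ms = decomp.ms("site_x_test_entry")
    else:
        gmo_ms = decomp.pooled_error_ms
    return gmo_ms / (s * b) + max(decomp.ms("genotype_within_reference"), 0.0) / (
        s * b * r
    )


def equivalence_limits(
    data: TrialDataset,
    alpha: float = 0.05,
    decomp: AnovaDecomposition | None = None,
    interaction_inflated: bool = False,
) -> tuple[float, float]:
    """Study-specific equivalence limits from reference-variety variation.

    ``+/- t(1 - alpha, r - 1) * sqrt(baseline + Var_hat(D))`` with
    baseline V_g_hat, or V_g_hat plus the site-by-reference interaction
    component in interaction-inflated mode.
    """
    if decomp is None:
        decomp = decompose(data)
    ref = estimate_reference_variation(data, decomp)
    vc = estimate_varcomps(decomp, data.design)
    baseline = ref.v_g
    if interaction_inflated:
        baseline += float(vc["sigma2_interaction_reference"])
    half = stats.t.ppf(1 - alpha, ref.df) * np.sqrt(
        baseline + _contrast_variance(decomp, interaction_inflated)
    )
    return (-float(half), float(half))


def equivalence_test(
    data: TrialDataset,
    alpha: float = 0.05,
    fixed_limits: tuple[float, float] | None = None,
    interaction_inflated: bool = False,
) -> EquivalenceResult:
    """TOST-style equivalence verdict for the GMO against the references.

    EQUIVALENT when the (1 - 2*alpha) CI for the GMO-minus-reference-mean
    difference lies entirely inside the limits; NOT_EQUIVALENT when it
    lies entirely outside on one side; INCONCLUSIVE otherwise.
    ``fixed_limits`` overrides the study-specific construction.
    """
    if not 0 < alpha < 0.5:
        raise DesignError(f"alpha must lie in (0, 0.5), got {alpha}")
    decomp = decompose(data)
    ref = estimate_reference_variation(data, decomp)
    cube = data.response_cube()
    est = float(
        cube[:, :, data.design.genotype_labels.index(data.design.gmo_label)].mean()
        - ref.mean
    )
    d = data.design
    s, b, r = d.n_sites, d.n_blocks_per_site, d.n_reference

    if fixed_limits is not None:
        # pre-specified limits: the reference set plays the role of a
        # fixed treatment, so its population variance stays out of the
        # contrast SE and the plot-error term supplies the df
        lo, hi = float(fixed_limits[0]), float(fixed_limits[1])
        if lo >= hi:
            raise DesignError(f"degenerate limits: lower {lo} >= upper {hi}")
        limits = (lo, hi)
        source = LimitsSource.USER_FIXED
        if interaction_inflated:
            gmo_ms, df_ci = decomp.ms("site_x_test_entry"), decomp.df(
                "site_x_test_entry"
            )
        else:
            gmo_ms, df_ci = decomp.pooled_error_ms, decomp.pooled_error_df
        se_d = float(np.sqrt(gmo_ms / (s * b) + gmo_ms / (s * b * r)))
    else:
        limits = equivalence_limits(data, alpha, decomp, interaction_inflated)
        source = LimitsSource.STUDY_SPECIFIC
        se_d = float(np.sqrt(_contrast_variance(decomp, interaction_inflated)))
        df_ci = ref.df

    crit = stats.t.ppf(1 - alpha, df_ci)
    ci = (est - crit * se_d, est + crit * se_d)

    if limits[0] < ci[0] and ci[1] < limits[1]:
        verdict = Verdict.EQUIVALENT
    elif ci[1] < limits[0] or ci[0] > limits[1]:
        verdict = Verdict.NOT_EQUIVALENT
    else:
        verdict = Verdict.INCONCLUSIVE
    return EquivalenceResult(
        estimate=est,
        confidence_interval=ci,
        limits=limits,
        v_g_estimate=ref.v_g,
        verdict=verdict,
        limits_source=source,
        alpha=alpha,
        interaction_inflated=interaction_inflated,
    )
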