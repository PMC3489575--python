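"""GMO-versus-comparator difference testing.

Two contested variants of the same test live here.  Both use the raw
mean difference between the GMO and the comparator; they differ only in
the error term:

* the **naive** test comes from the model with no site-by-genotype
  interaction, so its error term pools every interaction stratum with
  the plot error and carries the correspondingly large degrees of
  freedom.  When interaction variance is really present this error term
  is too small and the test rejects a true null far more often than its
  nominal size;
* the **interaction-aware** test uses the site-by-test-entry interaction
  mean square as the error term, on (s - 1) df for s sites and the two
  test entries.  In the balanced layout this is algebraically the paired
  t-test on the per-site GMO-minus-comparator differences, so it holds
  its level whatever the interaction variance.

The genotype-by-environment check ``gxe_interaction_test`` compares the
site-by-test-entry mean square against plot error, and can compute its
numerator by either of two routes — the closed-form balanced contrast
(sites as random deviations) or an all-fixed-effects OLS refit of the
test-entry subset — which give identical statistics in the balanced
case.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import AnovaDecomposition, decompose, decompose_cube, interaction_df
from .dataset import TrialDataset
from .design import DesignError, TrialDesign


class Method(enum.Enum):
    NAIVE = "naive"
    INTERACTION_AWARE = "interaction_aware"


@dataclass(frozen=True)
class DifferenceTestResult:
    """Outcome of a two-sided GMO-vs-comparator mean difference test."""

    estimate: float
    standard_error: float
    df: float
    t_statistic: float
    p_value: float
    confidence_interval: tuple[float, float]
    method: Method
    alpha: float

    def __str__(self) -> str:
        lo, hi = self.confidence_interval
        return (
            f"difference test ({self.method.value}): "
            f"estimate={self.estimate:.6g} se={self.standard_error:.6g} "
            f"df={self.df:g} t={self.t_statistic:.4g} p={self.p_value:.4g} "
            f"{100 * (1 - self.alpha):g}% CI [{lo:.6g}, {hi:.6g}]"
        )


def _check_alpha(alpha: float) -> None:
    if not 0 < alpha < 0.5:
        raise DesignError(f"alpha must lie in (0, 0.5), got {alpha}")


def _t_result(
    estimate: float, se: float, df: float, alpha: float, method: Method
) -> DifferenceTestResult:
    if se > 0:
        t = estimate / se
        p = 2.0 * stats.t.sf(abs(t), df)
    else:
        t = 0.0 if estimate == 0 else np.inf * np.sign(estimate)
        p = 1.0 if estimate == 0 else 0.0
    crit = stats.t.ppf(1 - alpha / 2.0, df)
    ci = (estimate - crit * se, estimate + crit * se)
    return DifferenceTestResult(
        estimate=estimate,
        standard_error=se,
        df=df,
        t_statistic=float(t),
        p_value=float(min(p, 1.0)),
        confidence_interval=ci,
        method=method,
        alpha=alpha,
    )


def mean_difference(cube: np.ndarray, design: TrialDesign) -> float:
    """Raw GMO-minus-comparator mean difference on the log scale."""
    k_gmo = design.genotype_labels.index(design.gmo_label)
    k_comp = design.genotype_labels.index(design.comparator_label)
    return float(cube[:, :, k_gmo].mean() - cube[:, :, k_comp].mean())


def difference_test_cube(
    cube: np.ndarray,
    design: TrialDesign,
    alpha: float = 0.1,
    method: Method | str = Method.NAIVE,
    decomp: AnovaDecomposition | None = None,
) -> DifferenceTestResult:
    """Closed-form difference test on a response cube (fast path)."""
    _check_alpha(alpha)
    method = Method(method)
    if decomp is None:
        decomp = decompose_cube(cube, design)
    s, b = design.n_sites, design.n_blocks_per_site
    est = mean_difference(cube, design)
    if method is Method.NAIVE:
        mse = decomp.pooled_error_ms
        df = decomp.pooled_error_df
    else:
        mse = decomp.ms("site_x_test_entry")
        df = interaction_df(s, 2)
    se = float(np.sqrt(2.0 * mse / (s * b)))
    return _t_result(est, se, df, alpha, method)


def naive_difference_test(
    data: TrialDataset, alpha: float = 0.1
) -> DifferenceTestResult:
    """Difference test from the no-interaction model.

    The error term pools all site-by-genotype interaction SS with plot
    error; SE^2 = 2 * MSE_pooled / (s * b) on the pooled df.
    """
    cube = data.response_cube()
    return difference_test_cube(cube, data.design, alpha, Method.NAIVE)


def interaction_aware_difference_test(
    data: TrialDataset, alpha: float = 0.1
) -> DifferenceTestResult:
    """Difference test with the site-by-test-entry error term.

    SE^2 = 2 * MS_SxT / (s * b) on (s - 1) df.  No pooling is performed
    when MS_SxT falls below the residual mean square; the printed error
    term is always the interaction mean square.
    """
    cube = data.response_cube()
    return difference_test_cube(cube, data.design, alpha, Method.INTERACTION_AWARE)


@dataclass(frozen=True)
class GxETestResult:
    """F test of the site-by-test-entry interaction against plot error."""

    statistic: float
    df_num: int
    df_den: int
    p_value: float
    site_effects: str  # labeling used for the numerator computation

    def __str__(self) -> str:
        return (
            f"GxE interaction test (site {self.site_effects}): "
            f"F({self.df_num}, {self.df_den}) = {self.statistic:.4g}, "
            f"p = {self.p_value:.4g}"
        )


def _sxt_ss_fixed_site(data: TrialDataset) -> tuple[float, int]:
    """Site-by-test-entry interaction SS via an all-fixed-effects OLS refit.

    Fits response ~ site + block-within-site + genotype + site:genotype on
    the GMO/comparator subset with statsmodels and reads the interaction
    row of the ANOVA table.  Balanced orthogonality makes this SS
    identical to the closed-form random-site contrast.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = data.design
    sub = data.frame[
        data.frame["genotype"].isin([d.gmo_label, d.comparator_label])
    ].copy()
    sub["site"] = sub["site"].astype(str)
    sub["block"] = sub["block"].astype(str)
    fit = smf.ols(
        "response ~ C(site) + C(site):C(block) + C(genotype) "
        "+ C(site):C(genotype)",
        data=sub,
    ).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    row = table.loc["C(site):C(genotype)"]
    return float(row["sum_sq"]), int(row["df"])


def gxe_interaction_test(
    data: TrialDataset, site_effects: str = "random"
) -> GxETestResult:
    """Test the GMO/comparator genotype-by-environment interaction.

    ``site_effects`` chooses the computational route for the numerator
    ("random": closed-form balanced contrast; "fixed": OLS refit with
    site as a fixed factor); the resulting statistic is the same either
    way in the balanced case.  The denominator is always the full-data
    plot-error mean square.
    """
    if site_effects not in ("random", "fixed"):
        raise DesignError(f"site_effects must be 'random' or 'fixed', got {site_effects!r}")
    decomp = decompose(data)
    if decomp.df("residual") <= 0:
        raise DesignError("zero residual degrees of freedom")
    if site_effects == "random":
        ss_num = decomp.ss("site_x_test_entry")
        df_num = decomp.df("site_x_test_entry")
    else:
        ss_num, df_num = _sxt_ss_fixed_site(data)
    ms_resid = decomp.ms("residual")
    df_den = decomp.df("residual")
    if ms_resid == 0:
        stat = np.inf if ss_num > 0 else 0.0
    else:
        stat = (ss_num / df_num) / ms_resid
    p = float(stats.f.sf(stat, df_num, df_den)) if np.isfinite(stat) else 0.0
    return GxETestResult(
        statistic=float(stat),
        df_num=int(df_num),
        df_den=int(df_den),
        p_value=p,
        site_effects=site_effects,
    )
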