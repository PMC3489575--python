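"""Balanced sums-of-squares decomposition, expected mean squares and
method-of-moments variance-component estimation.

The decomposition follows the trial mixed model with its two partitions:
the genotype stratum splits into genotype-group contrasts (fixed, 2 df)
and genotype-within-reference (random, r - 1 df); the site-by-genotype
stratum splits into

* ``site_x_test_entry`` — interaction of site with the GMO-vs-comparator
  contrast, (s - 1) df; this is the error stratum of the
  interaction-aware difference test,
* ``site_x_reference`` — interaction of site with the reference
  varieties, (s - 1)(r - 1) df,
* ``site_x_group_remainder`` — interaction of site with the
  test-pair-versus-reference-group contrast, (s - 1) df.

Everything is closed-form arithmetic on the balanced layout: the mean
squares, their expectations in terms of the variance components, and the
moment estimators that invert those expectations.  No iterative fitting
is involved, which makes the expected-mean-square map double as an exact
oracle for the decomposition itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import TrialDataset
from .design import DesignError, GenotypeGroup, TrialDesign, VarianceComponents

STRATA = (
    "site",
    "block_within_site",
    "genotype_group",
    "genotype_within_reference",
    "site_x_test_entry",
    "site_x_reference",
    "site_x_group_remainder",
    "residual",
)


class EstimationError(ValueError):
    """Raised when a quantity cannot be estimated from the design at hand."""


def interaction_df(n_sites: int, n_genotypes: int) -> int:
    """Degrees of freedom of a site-by-genotype interaction stratum.

    For ``s`` sites and ``t`` genotypes the stratum has (s - 1)(t - 1)
    df; with the two test entries (GMO and comparator) at four sites this
    is the 3 df carried by the interaction-aware difference test.
    """
    if n_sites < 2:
        raise DesignError(f"n_sites must be >= 2, got {n_sites}")
    if n_genotypes < 2:
        raise DesignError(f"n_genotypes must be >= 2, got {n_genotypes}")
    return (n_sites - 1) * (n_genotypes - 1)


@dataclass(frozen=True)
class AnovaDecomposition:
    """Stratum-wise SS / df / MS table for one balanced trial dataset."""

    table: pd.DataFrame  # index: STRATA; columns: ss, df, ms
    total_ss: float
    total_df: int
    design: TrialDesign

    def ss(self, stratum: str) -> float:
        return float(self.table.loc[stratum, "ss"])

    def df(self, stratum: str) -> int:
        return int(self.table.loc[stratum, "df"])

    def ms(self, stratum: str) -> float:
        return float(self.table.loc[stratum, "ms"])

    @property
    def interaction_ss(self) -> float:
        """Pooled site-by-genotype interaction SS, all three pieces."""
        return (
            self.ss("site_x_test_entry")
            + self.ss("site_x_reference")
            + self.ss("site_x_group_remainder")
        )

    @property
    def interaction_df_pooled(self) -> int:
        return (
            self.df("site_x_test_entry")
            + self.df("site_x_reference")
            + self.df("site_x_group_remainder")
        )

    @property
    def interaction_ms(self) -> float:
        return self.interaction_ss / self.interaction_df_pooled

    @property
    def pooled_error_ms(self) -> float:
        """Residual with all interaction folded in (the no-interaction model's
        error term, with correspondingly large df)."""
        return (self.interaction_ss + self.ss("residual")) / self.pooled_error_df

    @property
    def pooled_error_df(self) -> int:
        return self.interaction_df_pooled + self.df("residual")


def _stratum_dfs(design: TrialDesign) -> dict[str, int]:
    s, b = design.n_sites, design.n_blocks_per_site
    g, r = design.n_genotypes, design.n_reference
    return {
        "site": s - 1,
        "block_within_site": s * (b - 1),
        "genotype_group": 2,
        "genotype_within_reference": r - 1,
        "site_x_test_entry": s - 1,
        "site_x_reference": (s - 1) * (r - 1),
        "site_x_group_remainder": s - 1,
        "residual": s * (b - 1) * (g - 1),
    }


def decompose_cube(cube: np.ndarray, design: TrialDesign) -> AnovaDecomposition:
    """Balanced ANOVA of a ``(n_sites, n_blocks, n_genotypes)`` response array.

    Genotype axis order must match the design roster.  Pure arithmetic:
    marginal means, orthogonal contrast SS, residual by subtraction.
    """
    s, b, g = cube.shape
    if (s, b, g) != (
        design.n_sites,
        design.n_blocks_per_site,
        design.n_genotypes,
    ):
        raise DesignError("response cube shape does not match the design")
    r = design.n_reference
    groups = design.groups
    k_gmo = groups.index(GenotypeGroup.TEST_GMO)
    k_comp = groups.index(GenotypeGroup.TEST_COMPARATOR)
    ref_cols = [k for k, grp in enumerate(groups) if grp is GenotypeGroup.REFERENCE]

    grand = cube.mean()
    m_site = cube.mean(axis=(1, 2))  # (s,)
    m_block = cube.mean(axis=2)  # (s, b)
    m_geno = cube.mean(axis=(0, 1))  # (g,)
    m_cell = cube.mean(axis=1)  # (s, g)  site x genotype cell means

    total_ss = float(((cube - grand) ** 2).sum())
    ss_site = b * g * float(((m_site - grand) ** 2).sum())
    ss_block = g * float(((m_block - m_site[:, None]) ** 2).sum())
    ss_geno = s * b * float(((m_geno - grand) ** 2).sum())

    m_ref = m_geno[ref_cols].mean()
    ss_group = (
        s
        * b
        * (
            (m_geno[k_gmo] - grand) ** 2
            + (m_geno[k_comp] - grand) ** 2
            + r * (m_ref - grand) ** 2
        )
    )
    ss_gwr = s * b * float(((m_geno[ref_cols] - m_ref) ** 2).sum())

    inter = m_cell - m_site[:, None] - m_geno[None, :] + grand  # (s, g)
    ss_sxg = b * float((inter**2).sum())

    d_i = m_cell[:, k_gmo] - m_cell[:, k_comp]
    ss_sxt = (b / 2.0) * float(((d_i - d_i.mean()) ** 2).sum())

    ref_cells = m_cell[:, ref_cols]  # (s, r)
    w = (
        ref_cells
        - ref_cells.mean(axis=1, keepdims=True)
        - ref_cells.mean(axis=0, keepdims=True)
        + ref_cells.mean()
    )
    ss_sxref = b * float((w**2).sum())
    ss_rem = max(ss_sxg - ss_sxt - ss_sxref, 0.0)

    # residual computed directly (not by subtraction): within each site,
    # blocks and genotypes are crossed, so the fitted value of plot (i,j,k)
    # is m_block[i,j] + m_cell[i,k] - m_site[i]
    resid = cube - m_block[:, :, None] - m_cell[:, None, :] + m_site[:, None, None]
    ss_resid = float((resid**2).sum())

    dfs = _stratum_dfs(design)
    ss = {
        "site": ss_site,
        "block_within_site": ss_block,
        "genotype_group": ss_group,
        "genotype_within_reference": ss_gwr,
        "site_x_test_entry": ss_sxt,
        "site_x_reference": ss_sxref,
        "site_x_group_remainder": ss_rem,
        "residual": ss_resid,
    }
    table = pd.DataFrame(
        {
            "ss": [ss[st] for st in STRATA],
            "df": [dfs[st] for st in STRATA],
        },
        index=list(STRATA),
    )
    table["ms"] = np.where(table["df"] > 0, table["ss"] / table["df"], np.nan)
    return AnovaDecomposition(
        table=table,
        total_ss=total_ss,
        total_df=s * b * g - 1,
        design=design,
    )


def decompose(data: TrialDataset) -> AnovaDecomposition:
    """Balanced ANOVA decomposition of a trial dataset.

    Raises a :class:`~gmtrial.design.DesignError` for unbalanced or
    incomplete data — only complete balanced layouts have the closed-form
    decomposition; see docs/methods.md for the REML note on unbalanced
    designs.
    """
    try:
        cube = data.response_cube()
    except ValueError as exc:
        raise DesignError(
            "decompose requires a complete balanced dataset "
            f"(see the REML note in docs/methods.md): {exc}"
        ) from exc
    return decompose_cube(cube, data.design)


def expected_mean_squares(
    design: TrialDesign, varcomps: VarianceComponents
) -> dict[str, float]:
    """Expectation of every stratum mean square in terms of the components.

    Valid for the balanced layout with zero GMO/comparator offsets and
    RANDOM reference effects (the fixed genotype-group stratum otherwise
    gains a non-centrality term).
    """
    s, b = design.n_sites, design.n_blocks_per_site
    g, r = design.n_genotypes, design.n_reference
    vc = varcomps
    st, sr = vc.interaction_test, vc.interaction_reference
    se, sg = vc.sigma2_residual, vc.sigma2_genotype
    sbk, ssite = vc.sigma2_block, vc.sigma2_site

    # remainder contrast: (gmo+comp)/2 - reference mean; c'c = 1/2 + 1/r
    c2_rem = 0.5 + 1.0 / r
    w_rem = (st / 2.0 + sr / r) / c2_rem

    # genotype-group stratum = average of its two 1-df contrast EMS:
    # gmo-vs-comp, and the remainder contrast which also carries the
    # reference-population variance through the reference group mean
    ems_c1 = se + b * st
    ems_c2 = se + b * w_rem + s * b * (sg / r) / c2_rem
    return {
        "site": se + b * (2 * st + r * sr) / g + g * sbk + b * g * ssite,
        "block_within_site": se + g * sbk,
        "genotype_group": (ems_c1 + ems_c2) / 2.0,
        "genotype_within_reference": se + b * sr + s * b * sg,
        "site_x_test_entry": se + b * st,
        "site_x_reference": se + b * sr,
        "site_x_group_remainder": se + b * w_rem,
        "residual": se,
    }


@dataclass(frozen=True)
class VarianceEstimates:
    """Method-of-moments variance-component estimates.

    ``raw`` holds the untruncated EMS solutions (possibly negative);
    ``value`` truncates at zero, with ``truncated`` flagging where.
    """

    raw: dict[str, float]
    value: dict[str, float]
    truncated: dict[str, bool]

    def __getitem__(self, key: str) -> float:
        return self.value[key]


def estimate_varcomps(
    decomp: AnovaDecomposition, design: TrialDesign | None = None
) -> VarianceEstimates:
    """Solve the expected-mean-square equations for the components.

    Works stratum by stratum from the bottom of the table up; any negative
    solution is truncated to zero and flagged.  The interaction is always
    reported in partitioned form (``sigma2_interaction_test``,
    ``sigma2_interaction_reference``) plus the pooled single-component
    solution ``sigma2_interaction``.
    """
    design = design or decomp.design
    s, b = design.n_sites, design.n_blocks_per_site
    g, r = design.n_genotypes, design.n_reference
    if decomp.df("residual") <= 0:
        raise EstimationError("zero residual degrees of freedom")

    ms = {st: decomp.ms(st) for st in STRATA}
    raw: dict[str, float] = {}
    raw["sigma2_residual"] = ms["residual"]
    raw["sigma2_interaction_test"] = (ms["site_x_test_entry"] - ms["residual"]) / b
    if r >= 2:
        raw["sigma2_interaction_reference"] = (
            ms["site_x_reference"] - ms["residual"]
        ) / b
        raw["sigma2_genotype"] = (
            ms["genotype_within_reference"] - ms["site_x_reference"]
        ) / (s * b)
    else:
        raw["sigma2_interaction_reference"] = np.nan
        raw["sigma2_genotype"] = np.nan
    raw["sigma2_interaction"] = (decomp.interaction_ms - ms["residual"]) / b
    raw["sigma2_block"] = (ms["block_within_site"] - ms["residual"]) / g
    # site EMS inverted with the untruncated lower-stratum solutions
    st_hat = raw["sigma2_interaction_test"]
    sr_hat = raw["sigma2_interaction_reference"] if r >= 2 else st_hat
    raw["sigma2_site"] = (
        ms["site"]
        - raw["sigma2_residual"]
        - g * raw["sigma2_block"]
        - b * (2 * st_hat + r * sr_hat) / g
    ) / (b * g)

    value = {k: (0.0 if np.isfinite(v) and v < 0 else v) for k, v in raw.items()}
    truncated = {k: bool(np.isfinite(v) and v < 0) for k, v in raw.items()}
    return VarianceEstimates(raw=raw, value=value, truncated=truncated)
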