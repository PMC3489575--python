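"""Monte-Carlo rejection-rate and power estimation for the difference test.

The engine sweeps a grid of true GMO offsets (mu_GMO) crossed with
interaction-to-genotype variance ratios.  For each cell it simulates
``n_reps`` trials under the full mixed model with the site-by-genotype
interaction variance set to ``ratio * sigma2_genotype``, runs the chosen
difference test at the configured size, and records the rejection count
with its binomial standard error.  The mu_GMO = 0 column of each panel
is the empirical type-I error rate: for the naive test it climbs well
above the nominal level as soon as the ratio leaves zero, while the
interaction-aware test holds its level at every ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .anova import decompose_cube
from .design import DesignError, MeanStructure, VarianceComponents
from .difference import Method, difference_test_cube
from .simulate import SimulationConfig, simulate_response_cube

# mu_GMO grid with the alternating +0.02/+0.03 spacing
DEFAULT_MU_GRID = (0.0, 0.02, 0.05, 0.07, 0.10, 0.12, 0.15, 0.17, 0.20, 0.22, 0.25)
DEFAULT_RATIOS = (0.0, 0.5, 1.0)


def binomial_se(rate: float, n_reps: int) -> float:
    """Binomial standard error sqrt(rate * (1 - rate) / n_reps)."""
    if not 0.0 <= rate <= 1.0:
        raise DesignError(f"rate must lie in [0, 1], got {rate}")
    if n_reps < 1:
        raise DesignError(f"n_reps must be >= 1, got {n_reps}")
    return float(np.sqrt(rate * (1.0 - rate) / n_reps))


@dataclass(frozen=True)
class StudyGrid:
    """Monte-Carlo study layout: mu_GMO grid x interaction ratios."""

    base_config: SimulationConfig
    mu_gmo_values: tuple[float, ...] = DEFAULT_MU_GRID
    interaction_ratios: tuple[float, ...] = DEFAULT_RATIOS
    n_reps: int = 1000
    alpha: float = 0.1
    test_choice: Method = Method.NAIVE

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise DesignError(f"n_reps must be >= 1, got {self.n_reps}")
        if any(r < 0 for r in self.interaction_ratios):
            raise DesignError("interaction ratios must be >= 0")
        if not 0 < self.alpha <= 1:
            raise DesignError(f"alpha must lie in (0, 1], got {self.alpha}")


@dataclass(frozen=True)
class PowerStudyResult:
    """Per-cell rejection counts and rates of a Monte-Carlo study."""

    table: pd.DataFrame  # columns: mu_gmo, ratio, rejection_count, n_reps,
    #          rejection_rate, binomial_se, cell_seed
    grid: StudyGrid

    def rate(self, mu_gmo: float, ratio: float) -> float:
        t = self.table
        row = t[(t["mu_gmo"] == mu_gmo) & (t["ratio"] == ratio)]
        if len(row) != 1:
            raise KeyError((mu_gmo, ratio))
        return float(row["rejection_rate"].iloc[0])


def _cell_seed(base_seed: int, cell_index: int) -> int:
    """Deterministic per-cell seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(cell_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_power_study(grid: StudyGrid) -> PowerStudyResult:
    """Execute the Monte-Carlo sweep; deterministic given the base seed.

    Each (mu_gmo, ratio) cell draws its replicates from an independent
    seeded substream, so cells (and replicates within cells) can be
    reproduced in isolation.
    """
    base = grid.base_config
    rows = []
    cell_index = 0
    for ratio in grid.interaction_ratios:
        vc = replace(
            base.varcomps,
            sigma2_interaction=ratio * base.varcomps.sigma2_genotype,
            sigma2_interaction_test=None,
            sigma2_interaction_reference=None,
        )
        for mu in grid.mu_gmo_values:
            means = replace(base.means, mu_gmo_offset=mu)
            seed = _cell_seed(base.seed, cell_index)
            count = 0
            for rep in range(grid.n_reps):
                rng = np.random.default_rng([seed, rep])
                cube = simulate_response_cube(base.design, means, vc, rng)
                decomp = decompose_cube(cube, base.design)
                # the p-value does not depend on alpha; alpha=1 boundary
                # cells still reject every replicate since p < 1 a.s.
                res = difference_test_cube(
                    cube,
                    base.design,
                    alpha=grid.alpha if grid.alpha < 0.5 else 0.1,
                    method=grid.test_choice,
                    decomp=decomp,
                )
                if res.p_value < grid.alpha:
                    count += 1
            rate = count / grid.n_reps
            rows.append(
                {
                    "mu_gmo": mu,
                    "ratio": ratio,
                    "rejection_count": count,
                    "n_reps": grid.n_reps,
                    "rejection_rate": rate,
                    "binomial_se": binomial_se(rate, grid.n_reps),
                    "cell_seed": seed,
                }
            )
            cell_index += 1
    return PowerStudyResult(table=pd.DataFrame(rows), grid=grid)


def power_curve_table(result: PowerStudyResult) -> pd.DataFrame:
    """Tidy (mu_gmo, ratio, rate, se, n_reps) table for plotting/export."""
    cols = ["mu_gmo", "ratio", "rejection_rate", "binomial_se", "n_reps"]
    t = result.table.loc[:, cols].rename(
        columns={"rejection_rate": "rate", "binomial_se": "se"}
    )
    return t.reset_index(drop=True)


def plot_power_curves(result: PowerStudyResult, path: str | None = None):
    """One panel per interaction ratio: rejection rate vs mu_GMO.

    Returns the matplotlib Figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ratios = sorted(result.table["ratio"].unique())
    fig, axes = plt.subplots(
        1, len(ratios), figsize=(4 * len(ratios), 3.2), sharey=True, squeeze=False
    )
    for ax, ratio in zip(axes[0], ratios):
        sub = result.table[result.table["ratio"] == ratio].sort_values("mu_gmo")
        ax.errorbar(
            sub["mu_gmo"],
            sub["rejection_rate"],
            yerr=sub["binomial_se"],
            marker="o",
            lw=1,
        )
        ax.axhline(result.grid.alpha, color="grey", ls="--", lw=0.8)
        ax.set_title(f"interaction ratio = {ratio:g}")
        ax.set_xlabel(r"$\mu_{GMO}$")
        ax.set_ylim(0, 1)
    axes[0][0].set_ylabel("rejection rate")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
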