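"""Model/Results interface over the balanced trial analysis.

``TrialModel`` wraps one plot-level dataset; ``fit`` performs the
balanced ANOVA decomposition and method-of-moments variance-component
estimation and returns a ``TrialResults`` object from which the
difference tests, the genotype-by-environment check and the equivalence
test are available, statsmodels-style::

    model = TrialModel.from_dataframe(df)
    res = model.fit()
    print(res.summary())
    res.difference_test(method="interaction_aware", alpha=0.1)
    res.equivalence_test(alpha=0.05)
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import anova, difference, equivalence
from .anova import AnovaDecomposition, VarianceEstimates
from .dataset import TrialDataset, dataset_from_frame, validate_dataset
from .design import TrialDesign


class TrialModel:
    """Linear mixed model of a balanced multi-site GM crop trial.

    The model is Y_ijk = mean + site_i + block_ij + genotype_k +
    (site x genotype)_ik + e_ijk on log-scale responses, with the
    genotype stratum partitioned into the fixed three-level group factor
    (GMO / comparator / reference) and random variety effects within the
    reference group, and the interaction partitioned to match.
    """

    def __init__(self, data: TrialDataset):
        report = validate_dataset(data)
        if not report.ok:
            raise ValueError(f"invalid dataset:\n{report}")
        self.data = data
        self.design: TrialDesign = data.design

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, design: TrialDesign | None = None
    ) -> "TrialModel":
        return cls(dataset_from_frame(frame, design))

    @classmethod
    def from_csv(cls, path, design: TrialDesign | None = None) -> "TrialModel":
        from .io import read_trial_csv

        return cls(read_trial_csv(path, design))

    def fit(self) -> "TrialResults":
        decomp = anova.decompose(self.data)
        varcomps = anova.estimate_varcomps(decomp, self.design)
        return TrialResults(self, decomp, varcomps)


@dataclass
class TrialResults:
    """Fitted decomposition plus the tests that hang off it."""

    model: TrialModel
    decomposition: AnovaDecomposition
    variance_components: VarianceEstimates

    @property
    def anova_table(self) -> pd.DataFrame:
        return self.decomposition.table

    def difference_test(
        self, method: str | difference.Method = "interaction_aware", alpha: float = 0.1
    ) -> difference.DifferenceTestResult:
        m = difference.Method(method)
        if m is difference.Method.NAIVE:
            return difference.naive_difference_test(self.model.data, alpha)
        return difference.interaction_aware_difference_test(self.model.data, alpha)

    def gxe_test(self, site_effects: str = "random") -> difference.GxETestResult:
        return difference.gxe_interaction_test(self.model.data, site_effects)

    def equivalence_test(
        self,
        alpha: float = 0.05,
        fixed_limits: tuple[float, float] | None = None,
        interaction_inflated: bool = False,
    ) -> equivalence.EquivalenceResult:
        return equivalence.equivalence_test(
            self.model.data, alpha, fixed_limits, interaction_inflated
        )

    def summary(self, alpha: float = 0.1, equiv_alpha: float = 0.05) -> str:
        """Plain-text report: ANOVA table, variance components, tests."""
        d = self.model.design
        lines = [
            "Multi-site GM crop trial analysis",
            "=" * 70,
            f"sites: {d.n_sites}  blocks/site: {d.n_blocks_per_site}  "
            f"genotypes: {d.n_genotypes} "
            f"(1 GMO, 1 comparator, {d.n_reference} reference)",
            "",
            "Balanced ANOVA decomposition",
            "-" * 70,
            self.anova_table.to_string(float_format=lambda v: f"{v:.6g}"),
            "",
            "Variance components (method of moments, truncated at 0)",
            "-" * 70,
        ]
        for name, val in self.variance_components.value.items():
            flag = " [truncated]" if self.variance_components.truncated[name] else ""
            lines.append(f"  {name:32s} {val:.6g}{flag}")
        lines += [
            "",
            "Difference tests (GMO - comparator)",
            "-" * 70,
            "  " + str(self.difference_test("naive", alpha)),
            "  " + str(self.difference_test("interaction_aware", alpha)),
            "",
            "Genotype x environment interaction",
            "-" * 70,
            "  " + str(self.gxe_test()),
            "",
            "Equivalence vs reference population",
            "-" * 70,
        ]
        try:
            lines.append("  " + str(self.equivalence_test(equiv_alpha)))
            lines.append(
                "  "
                + str(self.equivalence_test(equiv_alpha, interaction_inflated=True))
            )
        except equivalence.EstimationError as exc:
            lines.append(f"  unavailable: {exc}")
        return "\n".join(lines)
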