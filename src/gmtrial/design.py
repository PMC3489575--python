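"""Domain types for multi-site GM crop trial designs.

A trial lays out one GM test entry, one conventional comparator and a set
of commercial reference varieties as a randomised complete block design
(RCBD) repeated at several sites.  Everything downstream (simulation,
balanced ANOVA, the difference and equivalence tests) assumes the complete
balanced layout: every genotype in every block at every site.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class GenotypeGroup(enum.Enum):
    """Three-level fixed classification of the genotypes in a trial."""

    TEST_GMO = "gmo"
    TEST_COMPARATOR = "comparator"
    REFERENCE = "reference"


class ReferenceEffectsMode(enum.Enum):
    """How reference-variety genotype effects enter the mean structure."""

    RANDOM = "random"
    FIXED = "fixed"


class DesignError(ValueError):
    """Raised when a design or configuration violates its invariants."""


@dataclass(frozen=True)
class TrialDesign:
    """Balanced multi-site RCBD layout with a genotype roster.

    Parameters
    ----------
    n_sites : int
        Number of sites (environments), at least 2.
    n_blocks_per_site : int
        Complete blocks nested within each site, at least 2.
    genotypes : tuple of (str, GenotypeGroup)
        Ordered roster; exactly one TEST_GMO, exactly one TEST_COMPARATOR
        and at least one REFERENCE entry.
    """

    n_sites: int
    n_blocks_per_site: int
    genotypes: tuple[tuple[str, GenotypeGroup], ...]
    balanced: bool = True

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise DesignError(f"n_sites must be >= 2, got {self.n_sites}")
        if self.n_blocks_per_site < 2:
            raise DesignError(
                f"n_blocks_per_site must be >= 2, got {self.n_blocks_per_site}"
            )
        if not self.balanced:
            raise DesignError("only complete balanced designs are supported")
        labels = [g for g, _ in self.genotypes]
        if len(set(labels)) != len(labels):
            raise DesignError("duplicate genotype labels in roster")
        counts = {grp: 0 for grp in GenotypeGroup}
        for _, grp in self.genotypes:
            counts[grp] += 1
        if counts[GenotypeGroup.TEST_GMO] != 1:
            raise DesignError("design requires exactly one TEST_GMO genotype")
        if counts[GenotypeGroup.TEST_COMPARATOR] != 1:
            raise DesignError("design requires exactly one TEST_COMPARATOR genotype")
        if counts[GenotypeGroup.REFERENCE] < 1:
            raise DesignError("design requires at least one REFERENCE genotype")

    # ------------------------------------------------------------------
    # roster helpers
    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_reference(self) -> int:
        return sum(1 for _, g in self.genotypes if g is GenotypeGroup.REFERENCE)

    @property
    def n_plots(self) -> int:
        return self.n_sites * self.n_blocks_per_site * self.n_genotypes

    @property
    def genotype_labels(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genotypes)

    @property
    def groups(self) -> tuple[GenotypeGroup, ...]:
        return tuple(grp for _, grp in self.genotypes)

    @property
    def gmo_label(self) -> str:
        return next(g for g, grp in self.genotypes if grp is GenotypeGroup.TEST_GMO)

    @property
    def comparator_label(self) -> str:
        return next(
            g for g, grp in self.genotypes if grp is GenotypeGroup.TEST_COMPARATOR
        )

    @property
    def reference_labels(self) -> tuple[str, ...]:
        return tuple(
            g for g, grp in self.genotypes if grp is GenotypeGroup.REFERENCE
        )

    def group_of(self, label: str) -> GenotypeGroup:
        for g, grp in self.genotypes:
            if g == label:
                return grp
        raise KeyError(label)


def build_design(n_sites: int, n_blocks: int, n_reference: int) -> TrialDesign:
    """Construct a balanced design with deterministic genotype labels.

    The roster is ``GMO``, ``COMP`` and ``REF01`` ... ``REFnn`` in that
    order; identical arguments always yield identical designs.
    """
    if n_sites < 2:
        raise DesignError(f"n_sites must be >= 2, got {n_sites}")
    if n_blocks < 2:
        raise DesignError(f"n_blocks must be >= 2, got {n_blocks}")
    if n_reference < 1:
        raise DesignError(f"n_reference must be >= 1, got {n_reference}")
    roster: list[tuple[str, GenotypeGroup]] = [
        ("GMO", GenotypeGroup.TEST_GMO),
        ("COMP", GenotypeGroup.TEST_COMPARATOR),
    ]
    width = max(2, len(str(n_reference)))
    roster.extend(
        (f"REF{i + 1:0{width}d}", GenotypeGroup.REFERENCE) for i in range(n_reference)
    )
    return TrialDesign(n_sites, n_blocks, tuple(roster))


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effect variances of the trial mixed model, log-scale units^2.

    The site-by-genotype interaction is parameterised either by a single
    pooled component ``sigma2_interaction`` or, mutually exclusively, by a
    partition into the site-by-test-entry component
    ``sigma2_interaction_test`` and the site-by-reference component
    ``sigma2_interaction_reference`` (interaction with site may differ
    between the test entries and the reference population).
    """

    sigma2_site: float = 0.0
    sigma2_block: float = 0.0
    sigma2_genotype: float = 0.0
    sigma2_interaction: float = 0.0
    sigma2_interaction_test: float | None = None
    sigma2_interaction_reference: float | None = None
    sigma2_residual: float = 0.0

    def __post_init__(self) -> None:
        part = (self.sigma2_interaction_test, self.sigma2_interaction_reference)
        if (part[0] is None) != (part[1] is None):
            raise DesignError(
                "sigma2_interaction_test and sigma2_interaction_reference "
                "must be supplied together"
            )
        if part[0] is not None and self.sigma2_interaction != 0.0:
            raise DesignError(
                "partitioned interaction components and a pooled "
                "sigma2_interaction are mutually exclusive"
            )
        for name in (
            "sigma2_site",
            "sigma2_block",
            "sigma2_genotype",
            "sigma2_interaction",
            "sigma2_residual",
        ):
            v = getattr(self, name)
            if v < 0:
                raise DesignError(f"{name} must be >= 0, got {v}")
        for name in ("sigma2_interaction_test", "sigma2_interaction_reference"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DesignError(f"{name} must be >= 0, got {v}")

    @property
    def partitioned(self) -> bool:
        return self.sigma2_interaction_test is not None

    @property
    def interaction_test(self) -> float:
        """Site-by-test-entry interaction variance, whichever parameterisation."""
        if self.partitioned:
            return float(self.sigma2_interaction_test)  # type: ignore[arg-type]
        return self.sigma2_interaction

    @property
    def interaction_reference(self) -> float:
        """Site-by-reference interaction variance, whichever parameterisation."""
        if self.partitioned:
            return float(self.sigma2_interaction_reference)  # type: ignore[arg-type]
        return self.sigma2_interaction


@dataclass(frozen=True)
class MeanStructure:
    """Fixed part of the model on the log scale.

    ``mu_overall`` is the grand mean; the GMO and comparator enter through
    fixed offsets.  Reference genotype effects are either drawn from a
    zero-mean population with variance ``sigma2_genotype`` (RANDOM mode,
    the default — references are a sample from the population of non-GM
    varieties) or supplied explicitly (FIXED mode).
    """

    mu_overall: float = 0.0
    mu_gmo_offset: float = 0.0
    mu_comparator_offset: float = 0.0
    reference_effects_mode: ReferenceEffectsMode = ReferenceEffectsMode.RANDOM
    reference_offsets: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if (
            self.reference_effects_mode is ReferenceEffectsMode.RANDOM
            and self.reference_offsets is not None
        ):
            raise DesignError(
                "explicit reference_offsets are not allowed in RANDOM mode"
            )
        if (
            self.reference_effects_mode is ReferenceEffectsMode.FIXED
            and self.reference_offsets is None
        ):
            raise DesignError("FIXED mode requires explicit reference_offsets")
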