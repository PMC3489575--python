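"""Simulation of plot-level trial data under the full mixed model.

Responses are generated on the log scale as

    Y_ijk = mu + Site_i + Block_ij + Genotype_k + (Site x Genotype)_ik + e_ijk

with site, block-within-site, interaction and plot-error effects drawn
independently from zero-mean normal distributions at the configured
variances.  The GMO and comparator carry fixed offsets; reference-variety
effects are, by default, fresh draws from a zero-mean normal with the
reference-population variance for every simulated dataset.  Setting the
interaction variance to zero reproduces the no-interaction generative
model whose omission of G-by-E structure is exactly what the difference
test critique turns on.

Random-number management: each replicate ``r`` of a batch uses the
independent stream ``default_rng([seed, r])``, so any replicate can be
regenerated in isolation and batches are embarrassingly parallel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .dataset import COLUMNS, TrialDataset
from .design import (
    DesignError,
    GenotypeGroup,
    MeanStructure,
    ReferenceEffectsMode,
    TrialDesign,
    VarianceComponents,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to simulate one trial dataset reproducibly."""

    design: TrialDesign
    means: MeanStructure
    varcomps: VarianceComponents
    seed: int = 0

    def __post_init__(self) -> None:
        if (
            self.means.reference_effects_mode is ReferenceEffectsMode.FIXED
            and len(self.means.reference_offsets or ())
            != self.design.n_reference
        ):
            raise DesignError(
                "reference_offsets length must equal the number of "
                "reference varieties in the design"
            )


def _interaction_sd_per_genotype(
    design: TrialDesign, vc: VarianceComponents
) -> np.ndarray:
    """Per-genotype standard deviation of the site-interaction effects."""
    sd = np.empty(design.n_genotypes)
    for k, grp in enumerate(design.groups):
        if grp is GenotypeGroup.REFERENCE:
            sd[k] = np.sqrt(vc.interaction_reference)
        else:
            sd[k] = np.sqrt(vc.interaction_test)
    return sd


def simulate_response_cube(
    design: TrialDesign,
    means: MeanStructure,
    varcomps: VarianceComponents,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one ``(n_sites, n_blocks, n_genotypes)`` response array.

    This is the hot path used by the Monte-Carlo engines; draw order is
    fixed (genotype, site, block, interaction, residual) so results are
    reproducible for a given generator state.
    """
    s, b = design.n_sites, design.n_blocks_per_site
    g = design.n_genotypes
    vc = varcomps

    geno = np.empty(g)
    ref_idx = 0
    for k, grp in enumerate(design.groups):
        if grp is GenotypeGroup.TEST_GMO:
            geno[k] = means.mu_gmo_offset
        elif grp is GenotypeGroup.TEST_COMPARATOR:
            geno[k] = means.mu_comparator_offset
        elif means.reference_effects_mode is ReferenceEffectsMode.FIXED:
            geno[k] = means.reference_offsets[ref_idx]  # type: ignore[index]
            ref_idx += 1
        else:
            geno[k] = rng.normal(0.0, np.sqrt(vc.sigma2_genotype))

    site = rng.normal(0.0, np.sqrt(vc.sigma2_site), size=s)
    block = rng.normal(0.0, np.sqrt(vc.sigma2_block), size=(s, b))
    inter = rng.normal(0.0, 1.0, size=(s, g)) * _interaction_sd_per_genotype(
        design, vc
    )
    resid = rng.normal(0.0, np.sqrt(vc.sigma2_residual), size=(s, b, g))

    return (
        means.mu_overall
        + geno[None, None, :]
        + site[:, None, None]
        + block[:, :, None]
        + inter[:, None, :]
        + resid
    )


def _cube_to_frame(cube: np.ndarray, design: TrialDesign) -> pd.DataFrame:
    s, b, g = cube.shape
    sites = np.repeat(np.arange(1, s + 1), b * g)
    blocks = np.tile(np.repeat(np.arange(1, b + 1), g), s)
    genos = np.tile(np.array(design.genotype_labels), s * b)
    groups = np.tile(np.array([grp.value for grp in design.groups]), s * b)
    return pd.DataFrame(
        {
            "site": sites,
            "block": blocks,
            "genotype": genos,
            "group": groups,
            "response": cube.reshape(-1),
        },
        columns=list(COLUMNS),
    )


def replicate_rng(seed: int, replicate: int = 0) -> np.random.Generator:
    """Independent generator for one replicate of a seeded batch."""
    return np.random.default_rng([seed, replicate])


def simulate_trial(config: SimulationConfig, replicate: int = 0) -> TrialDataset:
    """Simulate a single trial dataset under the configured mixed model.

    ``replicate`` selects the substream, so
    ``simulate_trial(cfg, r)`` equals the r-th element of
    ``simulate_batch(cfg, n)`` for any ``n > r``.
    """
    rng = replicate_rng(config.seed, replicate)
    cube = simulate_response_cube(config.design, config.means, config.varcomps, rng)
    return TrialDataset(_cube_to_frame(cube, config.design), config.design, config.seed)


def simulate_batch(config: SimulationConfig, n_reps: int) -> list[TrialDataset]:
    """Simulate ``n_reps`` independent datasets (one substream each)."""
    if n_reps < 1:
        raise DesignError(f"n_reps must be >= 1, got {n_reps}")
    return [simulate_trial(config, r) for r in range(n_reps)]


def iter_response_cubes(
    config: SimulationConfig, n_reps: int
) -> Iterator[np.ndarray]:
    """Yield raw response cubes for ``n_reps`` replicates (fast path)."""
    if n_reps < 1:
        raise DesignError(f"n_reps must be >= 1, got {n_reps}")
    for r in range(n_reps):
        rng = replicate_rng(config.seed, r)
        yield simulate_response_cube(
            config.design, config.means, config.varcomps, rng
        )
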