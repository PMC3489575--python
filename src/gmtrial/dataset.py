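"""Plot-level trial datasets and their validation.

A :class:`TrialDataset` holds one log-scale response per
(site, block, genotype) plot together with the :class:`~gmtrial.design.TrialDesign`
it conforms to.  The canonical in-memory form is a pandas DataFrame with
columns ``site, block, genotype, group, response``; the balanced-ANOVA
engine works on the equivalent ``(n_sites, n_blocks, n_genotypes)`` numpy
cube obtained from :meth:`TrialDataset.response_cube`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GenotypeGroup, TrialDesign

COLUMNS = ("site", "block", "genotype", "group", "response")


class DatasetError(ValueError):
    """Raised when a dataset cannot be interpreted against its design."""


@dataclass(frozen=True)
class ValidationReport:
    """Result of checking a dataset against the balanced-layout invariants."""

    missing_cells: tuple[tuple[int, int, str], ...] = ()
    duplicate_cells: tuple[tuple[int, int, str], ...] = ()
    nonfinite_cells: tuple[tuple[int, int, str], ...] = ()
    unexpected_cells: tuple[tuple[int, int, str], ...] = ()

    @property
    def ok(self) -> bool:
        return not (
            self.missing_cells
            or self.duplicate_cells
            or self.nonfinite_cells
            or self.unexpected_cells
        )

    def __str__(self) -> str:
        if self.ok:
            return "dataset valid: complete balanced layout, all responses finite"
        lines = []
        for name, cells in (
            ("missing", self.missing_cells),
            ("duplicated", self.duplicate_cells),
            ("non-finite response", self.nonfinite_cells),
            ("unexpected", self.unexpected_cells),
        ):
            for site, block, geno in cells:
                lines.append(f"{name} plot: site={site} block={block} genotype={geno}")
        return "\n".join(lines)


@dataclass(frozen=True)
class TrialDataset:
    """Plot-level records of a balanced multi-site RCBD trial.

    Parameters
    ----------
    frame : pandas.DataFrame
        Long-format table with columns ``site, block, genotype, group,
        response`` (response on the log scale).
    design : TrialDesign
        The layout the records conform to.
    seed : int, optional
        Seed provenance recorded by the simulator.
    """

    frame: pd.DataFrame
    design: TrialDesign
    seed: int | None = None

    @property
    def n_plots(self) -> int:
        return len(self.frame)

    def response_cube(self) -> np.ndarray:
        """Responses as an ``(n_sites, n_blocks, n_genotypes)`` array.

        Sites and blocks are ordered by their sorted unique labels;
        genotypes follow the design roster order.  Raises
        :class:`DatasetError` if the layout is not complete and balanced.
        """
        report = validate_dataset(self)
        if not report.ok:
            raise DatasetError(f"dataset is not complete/balanced:\n{report}")
        d = self.design
        geno_order = {g: k for k, g in enumerate(d.genotype_labels)}
        df = self.frame
        site_order = {s: i for i, s in enumerate(sorted(df["site"].unique()))}
        block_order = {
            (s, b): j
            for s in site_order
            for j, b in enumerate(
                sorted(df.loc[df["site"] == s, "block"].unique())
            )
        }
        cube = np.empty((d.n_sites, d.n_blocks_per_site, d.n_genotypes))
        i = df["site"].map(site_order).to_numpy()
        j = np.array(
            [block_order[(s, b)] for s, b in zip(df["site"], df["block"])]
        )
        k = df["genotype"].map(geno_order).to_numpy()
        cube[i, j, k] = df["response"].to_numpy(dtype=float)
        return cube

    def with_offset(self, delta: float) -> "TrialDataset":
        """Return a copy with ``delta`` added to every response."""
        df = self.frame.copy()
        df["response"] = df["response"] + delta
        return TrialDataset(df, self.design, self.seed)


def dataset_from_frame(
    frame: pd.DataFrame, design: TrialDesign | None = None, seed: int | None = None
) -> TrialDataset:
    """Build a :class:`TrialDataset`, inferring the design when not given.

    The inferred design orders genotypes GMO, comparator, then references
    in sorted label order.
    """
    missing = [c for c in COLUMNS if c not in frame.columns and c != "group"]
    if missing:
        raise DatasetError(f"missing required columns: {missing}")
    if design is None:
        if "group" not in frame.columns:
            raise DatasetError("cannot infer design without a 'group' column")
        design = _infer_design(frame)
    if "group" not in frame.columns:
        frame = frame.copy()
        frame["group"] = frame["genotype"].map(
            lambda g: design.group_of(g).value
        )
    return TrialDataset(frame.loc[:, list(COLUMNS)].reset_index(drop=True), design, seed)


def _infer_design(frame: pd.DataFrame) -> TrialDesign:
    group_map: dict[str, str] = {}
    for geno, grp in zip(frame["genotype"], frame["group"]):
        prev = group_map.setdefault(str(geno), str(grp))
        if prev != str(grp):
            raise DatasetError(
                f"genotype {geno!r} maps to more than one group ({prev!r}, {grp!r})"
            )
    by_group: dict[str, list[str]] = {"gmo": [], "comparator": [], "reference": []}
    for geno, grp in group_map.items():
        if grp not in by_group:
            raise DatasetError(
                f"unknown group label {grp!r}; expected gmo|comparator|reference"
            )
        by_group[grp].append(geno)
    if len(by_group["gmo"]) != 1 or len(by_group["comparator"]) != 1:
        raise DatasetError(
            "design inference requires exactly one gmo and one comparator genotype"
        )
    roster = [
        (by_group["gmo"][0], GenotypeGroup.TEST_GMO),
        (by_group["comparator"][0], GenotypeGroup.TEST_COMPARATOR),
    ] + [(g, GenotypeGroup.REFERENCE) for g in sorted(by_group["reference"])]
    n_sites = frame["site"].nunique()
    n_blocks = frame.groupby("site")["block"].nunique().max()
    return TrialDesign(int(n_sites), int(n_blocks), tuple(roster))


def validate_dataset(data: TrialDataset) -> ValidationReport:
    """Check a dataset for missing, duplicated or non-finite plot records.

    Returns a report listing every offending (site, block, genotype) cell;
    the report is empty exactly when the dataset satisfies the balanced
    complete-layout invariants.
    """
    d = data.design
    df = data.frame
    # expected grid: observed (site, block) pairs crossed with the roster;
    # integer labels 1..n fill in when the table carries no records at all
    pairs = sorted({(s, b) for s, b in zip(df["site"], df["block"])})
    if not pairs:
        pairs = [
            (s, b)
            for s in range(1, d.n_sites + 1)
            for b in range(1, d.n_blocks_per_site + 1)
        ]
    expected = {(s, b, g) for s, b in pairs for g in d.genotype_labels}
    seen: dict[tuple, int] = {}
    nonfinite = []
    for row in df.itertuples(index=False):
        key = (row.site, row.block, row.genotype)
        seen[key] = seen.get(key, 0) + 1
        if not np.isfinite(row.response):
            nonfinite.append(key)
    duplicates = sorted(k for k, n in seen.items() if n > 1)
    missing = sorted(expected - set(seen))
    unexpected = sorted(set(seen) - expected)
    if len(pairs) != d.n_sites * d.n_blocks_per_site and not missing:
        # whole blocks or sites absent: flag every cell of the shortfall
        missing = [("<any>", "<any>", g) for g in d.genotype_labels]  # type: ignore[list-item]
    return ValidationReport(
        missing_cells=tuple(missing),
        duplicate_cells=tuple(duplicates),
        nonfinite_cells=tuple(sorted(nonfinite)),
        unexpected_cells=tuple(unexpected),
    )
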