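"""CSV readers/writers and TOML configuration for trial data.

Datasets travel as RFC-4180 style CSV with a mandatory header
``site,block,genotype,group,response`` (response on the log scale;
group one of ``gmo|comparator|reference``).  Leading ``#`` comment
lines carry seed/config provenance and are ignored on read.  Unknown
columns are preserved on read but ignored by the analysis.
"""

from __future__ import annotations

import hashlib
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import COLUMNS, TrialDataset, dataset_from_frame
from .design import (
    DesignError,
    MeanStructure,
    TrialDesign,
    VarianceComponents,
    build_design,
)
from .simulate import SimulationConfig

VALID_GROUPS = ("gmo", "comparator", "reference")


class ParseError(ValueError):
    """Raised when a trial CSV cannot be parsed into a valid dataset."""


def read_trial_csv(path, design: TrialDesign | None = None) -> TrialDataset:
    """Read a long-format plot table into a validated TrialDataset.

    Errors name the offending row (1-based, counting the header as row 1)
    and column.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path,
            comment="#",
            dtype={"genotype": str, "group": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file, no header row") from exc
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    # row numbers in the raw file: header + 1-based data offset
    resp = pd.to_numeric(frame["response"], errors="coerce")
    bad = frame.index[resp.isna() & frame["response"].notna()]
    if len(bad):
        row = int(bad[0]) + 2
        raise ParseError(
            f"{path}: unparseable response {frame.loc[bad[0], 'response']!r} "
            f"at row {row}, column 'response'"
        )
    frame["response"] = resp
    bad_group = frame.index[~frame["group"].isin(VALID_GROUPS)]
    if len(bad_group):
        row = int(bad_group[0]) + 2
        raise ParseError(
            f"{path}: invalid group {frame.loc[bad_group[0], 'group']!r} at row "
            f"{row}, column 'group' (expected one of {'|'.join(VALID_GROUPS)})"
        )
    if frame["response"].isna().any():
        row = int(frame.index[frame["response"].isna()][0]) + 2
        raise ParseError(f"{path}: missing response at row {row}")
    return dataset_from_frame(frame, design)


def write_trial_csv(data: TrialDataset, path) -> None:
    """Write a dataset with deterministic row order and full precision.

    Rows are sorted by (site, block, roster order); responses render via
    Python's shortest round-trip float repr, so read-back is bit-exact.
    A leading comment line records the simulation seed when known.
    """
    path = Path(path)
    order = {g: k for k, g in enumerate(data.design.genotype_labels)}
    df = data.frame.copy()
    df["_k"] = df["genotype"].map(order)
    df = df.sort_values(["site", "block", "_k"], kind="stable").drop(columns="_k")
    with open(path, "w", newline="") as fh:
        if data.seed is not None:
            fh.write(f"# gmtrial dataset seed={data.seed}\n")
        df.to_csv(fh, index=False)


# ----------------------------------------------------------------------
# configuration

DEFAULT_CONFIG_PATH = Path(__file__).parent / "data" / "default_config.toml"


def config_digest(raw: bytes) -> str:
    return hashlib.sha256(raw).hexdigest()[:12]


def load_config(path=None) -> dict:
    """Load a TOML config, layered over the shipped defaults."""
    with open(DEFAULT_CONFIG_PATH, "rb") as fh:
        cfg = tomllib.load(fh)
    raw = DEFAULT_CONFIG_PATH.read_bytes()
    if path is not None:
        raw = Path(path).read_bytes()
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values)
    cfg["_digest"] = config_digest(raw)
    return cfg


def simulation_config_from_dict(cfg: dict, seed: int | None = None) -> SimulationConfig:
    d = cfg["design"]
    design = build_design(
        int(d["n_sites"]), int(d["n_blocks"]), int(d["n_reference"])
    )
    m = cfg["means"]
    means = MeanStructure(
        mu_overall=float(m["mu_overall"]),
        mu_gmo_offset=float(m["mu_gmo_offset"]),
        mu_comparator_offset=float(m["mu_comparator_offset"]),
    )
    v = cfg["varcomps"]
    kwargs = dict(
        sigma2_site=float(v["sigma2_site"]),
        sigma2_block=float(v["sigma2_block"]),
        sigma2_genotype=float(v["sigma2_genotype"]),
        sigma2_residual=float(v["sigma2_residual"]),
    )
    if "sigma2_interaction_test" in v or "sigma2_interaction_reference" in v:
        kwargs["sigma2_interaction_test"] = float(v.get("sigma2_interaction_test", 0))
        kwargs["sigma2_interaction_reference"] = float(
            v.get("sigma2_interaction_reference", 0)
        )
    else:
        kwargs["sigma2_interaction"] = float(v.get("sigma2_interaction", 0.0))
    varcomps = VarianceComponents(**kwargs)
    if seed is None:
        seed = int(cfg.get("simulation", {}).get("seed", 0))
    return SimulationConfig(design=design, means=means, varcomps=varcomps, seed=seed)
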