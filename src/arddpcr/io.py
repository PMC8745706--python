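"""File formats and run configuration.

Formats are deliberately plain: a QuantaSoft-export-like per-droplet CSV
(one row per droplet with well, sample and two channel amplitudes), YAML gate
files and assay/run configs, and tab-separated results tables.  Wells are
opaque labels; no plate geometry is modelled.  All numeric output uses ``.``
as the radix and no thousands separators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .assays import Channel
from .gating import GateSet
from .simulate import DropletSet, read_ground_truth, write_ground_truth

__all__ = [
    "DropletCSVDialect",
    "read_droplet_csv",
    "write_droplet_csv",
    "read_sample_sheet",
    "write_results",
    "read_results",
    "save_gates",
    "load_gates",
    "RunConfig",
    "run_config",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass(frozen=True)
class DropletCSVDialect:
    """Column naming of a per-droplet amplitude export."""

    well_col: str = "Well"
    sample_col: str = "Sample"
    ch1_col: str = "Ch1Amplitude"
    ch2_col: str = "Ch2Amplitude"
    delimiter: str = ","


def write_droplet_csv(
    droplet_sets: Iterable[DropletSet], path, dialect: DropletCSVDialect = DropletCSVDialect()
) -> None:
    frames = []
    for ds in droplet_sets:
        frames.append(pd.DataFrame({
            dialect.well_col: ds.well_id,
            dialect.sample_col: ds.sample_id,
            dialect.ch1_col: ds.ch1,
            dialect.ch2_col: ds.ch2,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep=dialect.delimiter, index=False)


def read_droplet_csv(
    path, dialect: DropletCSVDialect = DropletCSVDialect()
) -> dict[str, DropletSet]:
    """Load a droplet amplitude table into one DropletSet per well.

    Droplet order within each well is preserved.  A missing required column
    or a non-numeric amplitude fails with the column / line identified.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    for col in (dialect.well_col, dialect.sample_col, dialect.ch1_col, dialect.ch2_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out: dict[str, DropletSet] = {}
    for ch_col in (dialect.ch1_col, dialect.ch2_col):
        vals = pd.to_numeric(df[ch_col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy()))
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: non-numeric amplitude in column {ch_col!r} at line "
                f"{int(bad[0]) + 2}"
            )
        df[ch_col] = vals
    for well, grp in df.groupby(dialect.well_col, sort=False):
        out[str(well)] = DropletSet(
            well_id=str(well),
            sample_id=str(grp[dialect.sample_col].iloc[0]),
            ch1=grp[dialect.ch1_col].to_numpy(dtype=float),
            ch2=grp[dialect.ch2_col].to_numpy(dtype=float),
        )
    return out


# ---------------------------------------------------------------------------
# sample sheet

def read_sample_sheet(path, known_wells: Optional[set[str]] = None) -> pd.DataFrame:
    """Sample metadata table: sample_id, sex, disease_state, treatment flags
    and per-assay well lists ('+'-joined well ids).

    ``known_wells``, when given, must cover every referenced well.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    required = {"sample_id", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing sample-sheet column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id(s) {dupes}")
    if known_wells is not None:
        for col in (c for c in df.columns if c.endswith("_wells")):
            for cell in df[col]:
                for well in filter(None, str(cell).split("+")):
                    if well not in known_wells:
                        raise ValueError(f"{path}: unknown well {well!r} in {col}")
    return df


# ---------------------------------------------------------------------------
# results tables

_RESULT_COLUMNS = (
    "sample_id", "assay_id", "well_id", "target", "n_positive", "n_total",
    "copies_per_uL", "ci95_low", "ci95_high", "ar_ref_ratio", "cn",
    "amplified", "t877a_detected", "mutant_fraction", "chrx_cn",
)


def write_results(rows: Sequence[Mapping], path) -> None:
    """Write a deterministic-column-order TSV of per-sample/assay results.

    ``rows`` are mappings; the canonical columns come first in fixed order,
    any extra keys follow alphabetically.  Floats are written at 6
    significant digits, so the paired reader round-trips values to that
    precision.
    """
    df = pd.DataFrame(list(rows))
    extra = sorted(c for c in df.columns if c not in _RESULT_COLUMNS)
    cols = [c for c in _RESULT_COLUMNS if c in df.columns] + extra
    df = df.reindex(columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gate files

def save_gates(gates: GateSet, path) -> None:
    doc: dict = {"provenance": gates.provenance, "channels": {}}
    for ch in gates.cutpoints:
        doc["channels"][ch.name] = {
            "cutpoints": [float(x) for x in gates.cutpoints[ch]],
            "band_targets": [sorted(s) for s in gates.band_targets[ch]],
            "band_centers": [float(x) for x in gates.band_centers[ch]],
        }
    if gates.explicit_map is not None:
        doc["explicit_map"] = [
            {"ch1_band": i, "ch2_band": j, "targets": sorted(label)}
            for (i, j), label in sorted(gates.explicit_map.items())
        ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_gates(path) -> GateSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cutpoints, band_targets, band_centers = {}, {}, {}
    for name, spec in doc["channels"].items():
        ch = Channel[name]
        cutpoints[ch] = np.asarray(spec["cutpoints"], dtype=float)
        band_targets[ch] = tuple(frozenset(s) for s in spec["band_targets"])
        band_centers[ch] = np.asarray(spec["band_centers"], dtype=float)
    explicit = None
    if "explicit_map" in doc:
        explicit = {
            (e["ch1_band"], e["ch2_band"]): frozenset(e["targets"])
            for e in doc["explicit_map"]
        }
    return GateSet(
        cutpoints=cutpoints, band_targets=band_targets, band_centers=band_centers,
        provenance=doc.get("provenance", "manual"), explicit_map=explicit,
    )


# ---------------------------------------------------------------------------
# run configuration

@dataclass(frozen=True)
class RunConfig:
    """Validated run settings with conservative defaults."""

    assay_id: str = "AR-Amp-1/T877A"
    droplet_volume_uL: float = 0.00085
    amplification_threshold: float = 2.0
    min_mutant_droplets: int = 3
    seed: int = 0
    gate_file: Optional[str] = None

    def __post_init__(self) -> None:
        problems = []
        if self.droplet_volume_uL <= 0:
            problems.append("droplet_volume_uL must be positive")
        if self.amplification_threshold <= 0:
            problems.append("amplification_threshold must be positive")
        if self.min_mutant_droplets < 1:
            problems.append("min_mutant_droplets must be >= 1")
        if problems:
            raise ValueError("invalid run config: " + "; ".join(problems))


def run_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    allowed = {f.name for f in dc_fields(RunConfig)}
    unknown = sorted(set(doc) - allowed)
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    return RunConfig(**doc)
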