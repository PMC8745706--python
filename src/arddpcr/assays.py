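"""Declarative multiplex ddPCR assay definitions.

An assay is a set of fluorescently probed targets read on the two channels of a
droplet reader (CH1 = FAM, CH2 = HEX).  Amplitude multiplexing places several
targets on one channel at distinct intensity bands, so each target carries an
expected single-positive amplitude level.  Copy-number normalisation needs to
know, per target, how many alleles a normal diploid cell carries — 1 for
X-chromosomal targets in males, 2 otherwise — so that reference readings can be
rescaled for male X hemizygosity.

Two assays ship with the package:

``AR-Amp-1/T877A``
    AR exon 8 mutant (MT, FAM) and wild-type (WT, HEX) probes multiplexed with
    the chromosome-10 reference RPP30 (HEX).  Quantifies AR dosage and the
    T877A point mutation in one reaction.

``AR-Amp-2``
    Two independent AR amplicons, exon 1 (AR-X1) and exon 2 (AR-X2), both FAM,
    against two references: X-chromosomal MYM (ZMYM3) and chromosome-6 TBP,
    both HEX.  Cross-validates AR-Amp-1 and, via MYM, reports chromosome-X
    dosage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "Channel",
    "TargetRole",
    "TargetDef",
    "AssayDesign",
    "BUILTIN_ASSAY_IDS",
    "builtin_assay",
    "validate_assay",
    "assay_to_dict",
    "assay_from_dict",
    "save_assay",
    "load_assay",
]


class Channel(enum.IntEnum):
    """Droplet-reader optical channel (QX200 convention: CH1=FAM, CH2=HEX)."""

    CH1_FAM = 1
    CH2_HEX = 2


class TargetRole(str, enum.Enum):
    MUTANT = "mutant"
    WILDTYPE = "wildtype"
    GENE_TARGET = "gene_target"
    REFERENCE = "reference"


@dataclass(frozen=True)
class TargetDef:
    """One probed amplicon within a multiplex assay.

    Parameters
    ----------
    name
        Unique target identifier within the assay (e.g. ``"WT"``, ``"AR-X1"``).
    channel
        Detection channel of the conjugated dye.
    amplitude_level
        Expected fluorescence amplitude of the single-positive cluster above
        baseline, in arbitrary units.  Governs band placement for amplitude
        multiplexing; free parameter of the simulator.
    role
        Biological role; ``reference`` targets form the CN denominator.
    chromosome
        Chromosome label, e.g. ``"X"``, ``"10"``.
    alleles_per_normal_cell
        Copies per normal diploid cell, keyed by ``"male"``/``"female"``.
    """

    name: str
    channel: Channel
    amplitude_level: float
    role: TargetRole
    chromosome: str
    alleles_per_normal_cell: Mapping[str, int]

    def alleles(self, sex: str) -> int:
        return int(self.alleles_per_normal_cell[sex])


@dataclass(frozen=True)
class AssayDesign:
    """An ordered collection of targets plus free-form probe annotation."""

    assay_id: str
    targets: tuple[TargetDef, ...]
    probe_metadata: Mapping[str, Any] = field(default_factory=dict)

    def target(self, name: str) -> TargetDef:
        for t in self.targets:
            if t.name == name:
                return t
        raise KeyError(f"assay {self.assay_id!r} has no target {name!r}")

    @property
    def target_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.targets)

    @property
    def references(self) -> tuple[TargetDef, ...]:
        return tuple(t for t in self.targets if t.role is TargetRole.REFERENCE)

    def channel_targets(self, channel: Channel) -> tuple[TargetDef, ...]:
        return tuple(t for t in self.targets if t.channel is channel)


BUILTIN_ASSAY_IDS = ("AR-Amp-1/T877A", "AR-Amp-2")

_BUILTIN_FILES = {
    "AR-Amp-1/T877A": "ar_amp1_t877a.yaml",
    "AR-Amp-2": "ar_amp2.yaml",
}


def builtin_assay(assay_id: str) -> AssayDesign:
    """Load one of the two packaged assay designs by its identifier."""
    try:
        fname = _BUILTIN_FILES[assay_id]
    except KeyError:
        raise KeyError(
            f"unknown built-in assay {assay_id!r}; available: "
            f"{', '.join(BUILTIN_ASSAY_IDS)}"
        ) from None
    text = resources.files("arddpcr.data").joinpath(fname).read_text()
    assay = assay_from_dict(yaml.safe_load(text))
    violations = validate_assay(assay)
    if violations:  # pragma: no cover - packaged files are valid
        raise ValueError(f"packaged assay {assay_id!r} invalid: {violations}")
    return assay


def validate_assay(assay: AssayDesign) -> list[str]:
    """Check all design invariants; returns human-readable violations.

    An empty list means the design is usable for simulation, gating and CN
    calling.  Violations are returned rather than raised so callers can
    surface all problems at once.
    """
    v: list[str] = []
    names = [t.name for t in assay.targets]
    if len(set(names)) != len(names):
        v.append("target names are not unique")
    if not any(t.role is TargetRole.REFERENCE for t in assay.targets):
        v.append("assay has no reference target")
    for t in assay.targets:
        if not t.amplitude_level > 0:
            v.append(f"target {t.name}: amplitude_level must be > 0")
        for sex in ("male", "female"):
            if sex not in t.alleles_per_normal_cell:
                v.append(f"target {t.name}: missing allele count for {sex}")
            elif t.alleles_per_normal_cell[sex] not in (1, 2):
                v.append(f"target {t.name}: {sex} allele count must be 1 or 2")
        if t.chromosome == "X":
            if t.alleles_per_normal_cell.get("male") != 1:
                v.append(f"target {t.name}: X-chromosomal male allele count must be 1")
            if t.alleles_per_normal_cell.get("female") != 2:
                v.append(f"target {t.name}: X-chromosomal female allele count must be 2")
    for channel in Channel:
        levels = [t.amplitude_level for t in assay.channel_targets(channel)]
        if len(set(levels)) != len(levels):
            v.append(f"{channel.name}: amplitude levels within a channel must be distinct")
    return v


# ---------------------------------------------------------------------------
# serialisation

def assay_to_dict(assay: AssayDesign) -> dict:
    return {
        "assay_id": assay.assay_id,
        "targets": [
            {
                "name": t.name,
                "channel": t.channel.name,
                "amplitude_level": float(t.amplitude_level),
                "role": t.role.value,
                "chromosome": t.chromosome,
                "alleles_per_normal_cell": dict(t.alleles_per_normal_cell),
            }
            for t in assay.targets
        ],
        "probe_metadata": dict(assay.probe_metadata),
    }


def assay_from_dict(d: Mapping[str, Any]) -> AssayDesign:
    targets = tuple(
        TargetDef(
            name=td["name"],
            channel=Channel[td["channel"]],
            amplitude_level=float(td["amplitude_level"]),
            role=TargetRole(td["role"]),
            chromosome=str(td["chromosome"]),
            alleles_per_normal_cell={
                k: int(n) for k, n in td["alleles_per_normal_cell"].items()
            },
        )
        for td in d["targets"]
    )
    return AssayDesign(
        assay_id=d["assay_id"],
        targets=targets,
        probe_metadata=dict(d.get("probe_metadata", {})),
    )


def save_assay(assay: AssayDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(assay_to_dict(assay), fh, sort_keys=False)


def load_assay(path) -> AssayDesign:
    with open(path) as fh:
        return assay_from_dict(yaml.safe_load(fh))
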