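"""Synthetic droplet generator with known ground truth.

Emulates a QX200-style partitioned PCR: a well of ~20,000 droplets of ~0.85 nL
each, where every target's template count per droplet is Poisson with mean
``lambda = concentration [copies/uL] * droplet_volume [uL]``.  A droplet is
truth-positive for every target with at least one template copy.  Fluorescence
per channel is a baseline plus the sum of the amplitude levels of that
channel's positive targets (combination droplets stack additively), optionally
compressed by a saturation cap, plus Gaussian read noise.  "Rain" — droplets
with intermediate amplitude caused by partial amplification — can be injected
at a configurable rate and defaults to off.

Ground-truth labels ride along with every simulated well, so gating accuracy
and estimator calibration are directly measurable downstream.

Sample-level simulation starts from a genome profile (copies of each target
per diploid genome equivalent) and a genome concentration, covering normal
male/female genomes, cell-line-like profiles (T877A-mutant, AR-amplified) and
mass-ratio mixtures of two profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .assays import AssayDesign, Channel

__all__ = [
    "AmplitudeModel",
    "WellSpec",
    "DropletSet",
    "GenomeProfile",
    "GENOME_PROFILES",
    "simulate_well",
    "simulate_sample",
    "simulate_controls",
    "mix_profiles",
    "write_ground_truth",
    "read_ground_truth",
    "DEFAULT_DROPLET_VOLUME_UL",
    "DEFAULT_N_DROPLETS",
]

DEFAULT_DROPLET_VOLUME_UL = 0.00085  # 0.85 nL, QX200 nominal
DEFAULT_N_DROPLETS = 20000


@dataclass(frozen=True)
class AmplitudeModel:
    """Fluorescence model: per-channel baseline, noise, rain, saturation."""

    baseline: tuple[float, float] = (1000.0, 1000.0)
    noise_sd: tuple[float, float] = (120.0, 120.0)
    rain_fraction: float = 0.0
    saturation_cap: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.rain_fraction <= 1.0:
            raise ValueError("rain_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class WellSpec:
    """Template load of one simulated well: copies/uL per target, plus seed."""

    concentrations: Mapping[str, float]
    n_droplets: int = DEFAULT_N_DROPLETS
    droplet_volume_uL: float = DEFAULT_DROPLET_VOLUME_UL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if self.droplet_volume_uL <= 0:
            raise ValueError("droplet_volume_uL must be positive")


@dataclass
class DropletSet:
    """Two-channel amplitudes of one well, with optional ground truth."""

    well_id: str
    sample_id: str
    ch1: np.ndarray
    ch2: np.ndarray
    truth: Optional[list[frozenset[str]]] = None

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.ch1.shape != self.ch2.shape or self.ch1.ndim != 1:
            raise ValueError("ch1/ch2 must be 1-D arrays of equal length")
        if len(self.ch1) == 0:
            raise ValueError("a DropletSet must contain at least one droplet")
        if self.truth is not None and len(self.truth) != len(self.ch1):
            raise ValueError("truth labels must match droplet count")

    def __len__(self) -> int:
        return len(self.ch1)

    @property
    def amplitudes(self) -> np.ndarray:
        """(n, 2) array of (CH1, CH2) amplitudes."""
        return np.column_stack([self.ch1, self.ch2])


def simulate_well(
    assay: AssayDesign, spec: WellSpec, model: AmplitudeModel,
    *, well_id: str = "A01", sample_id: str = "sim",
) -> DropletSet:
    """Simulate one well under Poisson template partitioning.

    Draws, per target, an independent Poisson template count for every
    droplet; labels the droplet with the set of targets present; and renders
    the two channel amplitudes additively.  Identical arguments (including
    ``spec.seed``) give bit-identical output.
    """
    known = set(assay.target_names)
    for name, conc in spec.concentrations.items():
        if name not in known:
            raise KeyError(f"concentration given for unknown target {name!r}")
        if conc < 0:
            raise ValueError(f"negative concentration for target {name!r}")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_droplets
    positive = {}
    for t in assay.targets:  # fixed draw order for determinism
        lam = spec.concentrations.get(t.name, 0.0) * spec.droplet_volume_uL
        positive[t.name] = rng.poisson(lam, size=n) >= 1

    channels = {}
    for idx, channel in enumerate(Channel):
        signal = np.zeros(n)
        for t in assay.channel_targets(channel):
            signal += np.where(positive[t.name], t.amplitude_level, 0.0)
        if model.rain_fraction > 0:
            pos_any = signal > 0
            is_rain = pos_any & (rng.random(n) < model.rain_fraction)
            signal = np.where(is_rain, signal * rng.random(n), signal)
        if model.saturation_cap is not None:
            cap = model.saturation_cap[idx] - model.baseline[idx]
            max_single = max(
                (t.amplitude_level for t in assay.channel_targets(channel)),
                default=0.0,
            )
            if cap <= max_single:
                raise ValueError("saturation_cap must exceed the largest band")
            signal = np.minimum(signal, cap)
        amp = model.baseline[idx] + signal + rng.normal(0.0, model.noise_sd[idx], n)
        channels[channel] = amp

    truth = _labels_from_positive(assay, positive, n)
    return DropletSet(
        well_id=well_id,
        sample_id=sample_id,
        ch1=channels[Channel.CH1_FAM],
        ch2=channels[Channel.CH2_HEX],
        truth=truth,
    )


def _labels_from_positive(assay, positive, n) -> list[frozenset[str]]:
    # shared frozenset objects per combination keep this O(n) dict lookups
    names = assay.target_names
    mask = np.zeros(n, dtype=np.int64)
    for j, t in enumerate(names):
        mask |= positive[t].astype(np.int64) << j
    lut = {
        m: frozenset(names[j] for j in range(len(names)) if m >> j & 1)
        for m in np.unique(mask)
    }
    return [lut[m] for m in mask]


# ---------------------------------------------------------------------------
# genome-profile-level simulation

@dataclass(frozen=True)
class GenomeProfile:
    """Copies of each target per diploid genome equivalent, plus donor sex."""

    copies_per_genome: Mapping[str, float]
    sex: str = "male"

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.copies_per_genome.values()):
            raise ValueError("copies per genome must be non-negative")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")


#: Stylised genome profiles used throughout the worked analyses.  Values are
#: copies per diploid genome equivalent; the cancer-line profiles encode the
#: dosage relationships of the characterised lines (T877A-hemizygous
#: polyploid LNCaP-like; highly AR-amplified VCaP-like; moderately amplified
#: female-derived MFM-223-like), not measured absolute copies.
GENOME_PROFILES: dict[str, GenomeProfile] = {
    "male_normal": GenomeProfile(
        {"MT": 0, "WT": 1, "RPP30": 2, "AR-X1": 1, "AR-X2": 1, "MYM": 1, "TBP": 2},
        sex="male",
    ),
    "female_normal": GenomeProfile(
        {"MT": 0, "WT": 2, "RPP30": 2, "AR-X1": 2, "AR-X2": 2, "MYM": 2, "TBP": 2},
        sex="female",
    ),
    "lncap_like": GenomeProfile(
        {"MT": 2, "WT": 0, "RPP30": 4, "AR-X1": 2, "AR-X2": 2, "MYM": 2, "TBP": 4},
        sex="male",
    ),
    "vcap_like": GenomeProfile(
        {"MT": 0, "WT": 27.5, "RPP30": 2, "AR-X1": 26, "AR-X2": 26, "MYM": 1.3, "TBP": 2},
        sex="male",
    ),
    "mfm223_like": GenomeProfile(
        {"MT": 0, "WT": 7.7, "RPP30": 2, "AR-X1": 7.5, "AR-X2": 7.5, "MYM": 2.2, "TBP": 2},
        sex="female",
    ),
}


def mix_profiles(
    a: GenomeProfile, b: GenomeProfile, mass_ratio: tuple[float, float] = (2, 1)
) -> GenomeProfile:
    """Mass-ratio mixture of two genome profiles (gDNA spike-in style).

    Genome equivalents are taken proportional to DNA mass, so the mixture's
    per-genome copy profile is the mass-weighted mean.  The returned sex is
    profile ``a``'s (the majority component in the 2:1 spike-ins).
    """
    wa, wb = mass_ratio
    if wa < 0 or wb < 0 or wa + wb == 0:
        raise ValueError("mass ratio weights must be non-negative, not both zero")
    names = set(a.copies_per_genome) | set(b.copies_per_genome)
    mixed = {
        t: (wa * a.copies_per_genome.get(t, 0.0) + wb * b.copies_per_genome.get(t, 0.0))
        / (wa + wb)
        for t in names
    }
    return GenomeProfile(mixed, sex=a.sex)


def simulate_sample(
    assay: AssayDesign,
    profile: GenomeProfile,
    genome_equivalents_per_uL: float,
    *,
    seed: int = 0,
    n_droplets: int = DEFAULT_N_DROPLETS,
    droplet_volume_uL: float = DEFAULT_DROPLET_VOLUME_UL,
    model: AmplitudeModel | None = None,
    well_id: str = "A01",
    sample_id: str = "sim",
) -> DropletSet:
    """Simulate a well from a genome profile and genome concentration.

    ``copies/uL`` of target T is ``copies_per_genome[T] *
    genome_equivalents_per_uL``; targets the assay does not carry are ignored.
    """
    if genome_equivalents_per_uL < 0:
        raise ValueError("genome_equivalents_per_uL must be non-negative")
    conc = {
        t.name: profile.copies_per_genome.get(t.name, 0.0) * genome_equivalents_per_uL
        for t in assay.targets
    }
    spec = WellSpec(
        concentrations=conc,
        n_droplets=n_droplets,
        droplet_volume_uL=droplet_volume_uL,
        seed=seed,
    )
    return simulate_well(
        assay, spec, model or AmplitudeModel(), well_id=well_id, sample_id=sample_id
    )


def simulate_controls(
    assay: AssayDesign,
    *,
    seed: int = 0,
    copies_per_uL: float = 400.0,
    n_droplets_per_control: int = 5000,
    model: AmplitudeModel | None = None,
) -> DropletSet:
    """Simulate a merged control set: one negative well plus one
    single-target well per assay target, concatenated with truth labels.

    Mirrors the bench practice of running water blanks and single-probe
    positive controls to anchor thresholds in each run.
    """
    model = model or AmplitudeModel()
    wells = []
    for i, name in enumerate((None, *assay.target_names)):
        conc = {} if name is None else {name: copies_per_uL}
        spec = WellSpec(
            concentrations=conc,
            n_droplets=n_droplets_per_control,
            seed=seed * 1009 + i,
        )
        wells.append(simulate_well(assay, spec, model, well_id=f"C{i:02d}",
                                   sample_id="control" if name is None else f"control-{name}"))
    ch1 = np.concatenate([w.ch1 for w in wells])
    ch2 = np.concatenate([w.ch2 for w in wells])
    truth: list[frozenset[str]] = []
    for w in wells:
        truth.extend(w.truth)  # type: ignore[arg-type]
    return DropletSet(well_id="CTRL", sample_id="controls", ch1=ch1, ch2=ch2, truth=truth)


# ---------------------------------------------------------------------------
# ground-truth sidecar

_EMPTY_LABEL = "."


def write_ground_truth(ds: DropletSet, path) -> None:
    """Write a one-row-per-droplet sidecar of truth labels ('+'-joined;
    '.' for empty droplets)."""
    if ds.truth is None:
        raise ValueError("DropletSet carries no ground-truth labels")
    with open(path, "w") as fh:
        fh.write("droplet_index\tlabel\n")
        for i, label in enumerate(ds.truth):
            text = "+".join(sorted(label)) if label else _EMPTY_LABEL
            fh.write(f"{i}\t{text}\n")


def read_ground_truth(path) -> list[frozenset[str]]:
    labels = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("droplet_index"):
            raise ValueError(f"{path}: not a ground-truth sidecar")
        for line in fh:
            _, text = line.rstrip("\n").split("\t")
            labels.append(frozenset() if text == _EMPTY_LABEL else frozenset(text.split("+")))
    return labels
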