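"""Amplitude gating: droplet -> population label.

Reproduces, deterministically, what an operator does in the instrument
software: set per-channel thresholds between amplitude bands using the run's
positive and negative controls, then read off each droplet's population from
the band it falls in on each channel.  With amplitude multiplexing the bands
of one channel are the subset sums of that channel's single-target levels
(combination droplets stack additively), so k same-channel targets give up to
2**k bands and a two-channel assay yields a full grid of candidate
populations — most of which are only occupied at high template load.

Band centers are fitted from controls either from simulator truth labels or,
absent truth, by 1-D k-means per channel (controls must then contain the
negative population and each single-positive population).  Cut points sit at
midpoints between adjacent enumerated band centers; a channel whose adjacent
bands come closer than a minimum number of pooled noise SDs is rejected as
inseparable rather than silently gated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .assays import AssayDesign, Channel
from .simulate import DropletSet

__all__ = [
    "GateSet",
    "PopulationCounts",
    "GatingResult",
    "InseparableBandsError",
    "InsufficientControlsError",
    "derive_gates",
    "manual_gates",
    "call_populations",
    "positive_counts",
]


class InseparableBandsError(ValueError):
    """Adjacent amplitude bands are too close to be gated apart."""


class InsufficientControlsError(ValueError):
    """Controls lack the negative or a single-positive population."""


@dataclass(frozen=True)
class GateSet:
    """Per-channel band boundaries and the band -> target-set map.

    ``cutpoints[ch]`` is a strictly increasing array of amplitude cuts
    defining ``len+1`` bands; ``band_targets[ch][i]`` is the target set of
    band ``i``; ``band_centers[ch][i]`` its expected center amplitude.  A
    droplet in (CH1 band i, CH2 band j) is labelled with the union of the two
    bands' target sets, unless an explicit (i, j) -> label map is supplied
    (manual gates), in which case unmapped grid cells are resolved to the
    nearest expected center and flagged.
    """

    cutpoints: Mapping[Channel, np.ndarray]
    band_targets: Mapping[Channel, tuple[frozenset[str], ...]]
    band_centers: Mapping[Channel, np.ndarray]
    provenance: str = "derived-from-controls"
    explicit_map: Optional[Mapping[tuple[int, int], frozenset[str]]] = None

    def __post_init__(self) -> None:
        for ch in self.cutpoints:
            cuts = np.asarray(self.cutpoints[ch], dtype=float)
            if np.any(np.diff(cuts) <= 0):
                raise ValueError(f"{ch.name}: cut points must be strictly increasing")
            if len(self.band_targets[ch]) != len(cuts) + 1:
                raise ValueError(f"{ch.name}: need one band label per band")
            if self.band_targets[ch][0]:
                raise ValueError(f"{ch.name}: lowest band must be the negative band")

    def label_of(self, i: int, j: int) -> Optional[frozenset[str]]:
        if self.explicit_map is not None:
            return self.explicit_map.get((i, j))
        return self.band_targets[Channel.CH1_FAM][i] | self.band_targets[Channel.CH2_HEX][j]


@dataclass(frozen=True)
class PopulationCounts:
    """Droplet counts per population label; labels partition the well."""

    counts: Mapping[frozenset[str], int]
    n_total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_total:
            raise ValueError("population counts must sum to n_total")

    def get(self, label) -> int:
        return self.counts.get(frozenset(label), 0)


@dataclass(frozen=True)
class GatingResult:
    labels: list[frozenset[str]]
    counts: PopulationCounts
    flagged: np.ndarray  # True where the band combination was unmapped


def _enumerate_bands(
    baseline: float, levels: dict[str, float], min_gap: float, channel: Channel
) -> tuple[np.ndarray, tuple[frozenset[str], ...]]:
    """All subset-sum band centers of one channel, sorted ascending."""
    names = sorted(levels, key=levels.get)
    combos = []
    for r in range(len(names) + 1):
        for subset in itertools.combinations(names, r):
            combos.append((baseline + sum(levels[t] for t in subset), frozenset(subset)))
    combos.sort(key=lambda c: c[0])
    centers = np.array([c[0] for c in combos])
    if len(centers) > 1 and np.min(np.diff(centers)) < min_gap:
        raise InseparableBandsError(
            f"{channel.name}: adjacent bands separated by less than the "
            f"minimum gap ({min_gap:.0f}); amplitude multiplexing not separable"
        )
    return centers, tuple(c[1] for c in combos)


def derive_gates(
    controls: DropletSet,
    assay: AssayDesign,
    *,
    min_separation_sd: float = 4.0,
    min_cluster_droplets: int = 20,
) -> GateSet:
    """Fit band centers from control droplets and place midpoint cuts.

    With truth labels, the negative and each single-positive population give
    the baseline and per-target levels directly.  Without truth, each channel
    is clustered by 1-D k-means into (1 + number of targets on the channel)
    levels, which requires the controls to contain every single-positive
    population (e.g. merged single-probe control wells).
    """
    cutpoints, band_targets, band_centers = {}, {}, {}
    for channel in Channel:
        amp = controls.ch1 if channel is Channel.CH1_FAM else controls.ch2
        targets = assay.channel_targets(channel)
        if controls.truth is not None:
            neg = np.array([not lab for lab in controls.truth])
            if neg.sum() < min_cluster_droplets:
                raise InsufficientControlsError("controls lack a negative population")
            baseline = float(amp[neg].mean())
            sds = [float(amp[neg].std(ddof=1))]
            levels = {}
            for t in targets:
                sel = np.array([lab == {t.name} for lab in controls.truth])
                if sel.sum() < min_cluster_droplets:
                    raise InsufficientControlsError(
                        f"controls lack a single-positive population for {t.name!r}"
                    )
                levels[t.name] = float(amp[sel].mean()) - baseline
                sds.append(float(amp[sel].std(ddof=1)))
            pooled_sd = float(np.sqrt(np.mean(np.square(sds))))
        else:
            baseline, levels, pooled_sd = _kmeans_levels(
                amp, targets, min_cluster_droplets
            )
        centers, labels = _enumerate_bands(
            baseline, levels, min_separation_sd * pooled_sd, channel
        )
        cutpoints[channel] = (centers[:-1] + centers[1:]) / 2.0
        band_targets[channel] = labels
        band_centers[channel] = centers
    return GateSet(
        cutpoints=cutpoints,
        band_targets=band_targets,
        band_centers=band_centers,
        provenance="derived-from-controls",
    )


def _kmeans_levels(amp, targets, min_cluster_droplets):
    from sklearn.cluster import KMeans

    k = 1 + len(targets)
    km = KMeans(n_clusters=k, n_init=10, random_state=0)
    assign = km.fit_predict(amp.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    centers = km.cluster_centers_.ravel()[order]
    sizes = np.bincount(assign, minlength=k)[order]
    if np.any(sizes < min_cluster_droplets):
        raise InsufficientControlsError(
            "k-means found an underpopulated amplitude band; controls must "
            "contain the negative and every single-positive population"
        )
    baseline = float(centers[0])
    # targets ranked by declared level get the fitted centers in order
    ranked = sorted(targets, key=lambda t: t.amplitude_level)
    levels = {t.name: float(c) - baseline for t, c in zip(ranked, centers[1:])}
    sds = [float(amp[assign == lbl].std(ddof=1)) for lbl in np.arange(k)]
    pooled_sd = float(np.sqrt(np.mean(np.square(sds))))
    return baseline, levels, pooled_sd


def manual_gates(
    cutpoints: Mapping[Channel, Sequence[float]],
    band_targets: Mapping[Channel, Sequence[frozenset[str]]],
    band_centers: Mapping[Channel, Sequence[float]] | None = None,
    explicit_map: Mapping[tuple[int, int], frozenset[str]] | None = None,
) -> GateSet:
    """Build a GateSet from operator-supplied cut points (audit parity with
    manual thresholding)."""
    cuts = {ch: np.asarray(v, dtype=float) for ch, v in cutpoints.items()}
    bands = {ch: tuple(frozenset(s) for s in v) for ch, v in band_targets.items()}
    if band_centers is None:
        band_centers = {}
        for ch, c in cuts.items():
            edges = np.concatenate([[c[0] - (c[1] - c[0]) if len(c) > 1 else c[0] - 1.0],
                                    c, [c[-1] + (c[-1] - c[-2]) if len(c) > 1 else c[-1] + 1.0]])
            band_centers[ch] = (edges[:-1] + edges[1:]) / 2.0
    centers = {ch: np.asarray(v, dtype=float) for ch, v in band_centers.items()}
    return GateSet(
        cutpoints=cuts, band_targets=bands, band_centers=centers,
        provenance="manual", explicit_map=explicit_map,
    )


def call_populations(ds: DropletSet, gates: GateSet) -> GatingResult:
    """Label every droplet with its population (target-name set).

    Droplets landing in a grid cell without an explicit label (possible only
    with manual gates) are assigned to the nearest expected combination
    center in amplitude space and flagged, never dropped: they stay in the
    denominator so the Poisson negative fraction is unbiased.
    """
    cuts1 = gates.cutpoints[Channel.CH1_FAM]
    cuts2 = gates.cutpoints[Channel.CH2_HEX]
    b1 = np.searchsorted(cuts1, ds.ch1)
    b2 = np.searchsorted(cuts2, ds.ch2)

    n2 = len(gates.band_targets[Channel.CH2_HEX])
    cells = b1 * n2 + b2
    uniq, inverse, cell_counts = np.unique(cells, return_inverse=True, return_counts=True)

    cell_labels: list[frozenset[str]] = []
    cell_flag = np.zeros(len(uniq), dtype=bool)
    for k, c in enumerate(uniq):
        i, j = int(c) // n2, int(c) % n2
        label = gates.label_of(i, j)
        if label is None:
            label = _nearest_mapped_label(gates, i, j)
            cell_flag[k] = True
        cell_labels.append(label)

    labels = [cell_labels[k] for k in inverse]
    counts: dict[frozenset[str], int] = {}
    for k, c in zip(range(len(uniq)), cell_counts):
        counts[cell_labels[k]] = counts.get(cell_labels[k], 0) + int(c)
    return GatingResult(
        labels=labels,
        counts=PopulationCounts(counts=counts, n_total=len(ds)),
        flagged=cell_flag[inverse],
    )


def _nearest_mapped_label(gates: GateSet, i: int, j: int) -> frozenset[str]:
    """Resolve an unmapped band cell to the mapped cell with the nearest
    expected center (Euclidean in amplitude space)."""
    assert gates.explicit_map is not None
    c1 = gates.band_centers[Channel.CH1_FAM]
    c2 = gates.band_centers[Channel.CH2_HEX]
    best, best_d = None, np.inf
    for (bi, bj), label in gates.explicit_map.items():
        d = (c1[bi] - c1[i]) ** 2 + (c2[bj] - c2[j]) ** 2
        if d < best_d:
            best, best_d = label, d
    if best is None:
        raise ValueError("gate set maps no band combination at all")
    return best


def positive_counts(
    pc: PopulationCounts, assay: AssayDesign
) -> dict[str, tuple[int, int]]:
    """Per-target (n_positive, n_total): a combination droplet counts once
    toward every member target."""
    out = {}
    for t in assay.target_names:
        n_pos = sum(c for label, c in pc.counts.items() if t in label)
        out[t] = (n_pos, pc.n_total)
    return out
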