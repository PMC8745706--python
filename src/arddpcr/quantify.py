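"""Poisson-corrected target quantification from droplet counts.

Digital PCR infers concentration from occupancy: with templates partitioned
Poisson across droplets of volume V, the mean copies per droplet is
``lambda = -ln(1 - p)`` where ``p`` is the positive-droplet fraction, and the
concentration is ``lambda / V`` copies per microlitre of reaction.  The
default 95% CI propagates the normal approximation on ``p`` through the log
transform (the convention of instrument software); an exact Clopper-Pearson
interval is available behind a flag.  Replicate wells are merged by pooling
positives and totals before correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .assays import AssayDesign
from .gating import GateSet, call_populations, positive_counts
from .simulate import DEFAULT_DROPLET_VOLUME_UL, DropletSet

__all__ = [
    "TargetConcentration",
    "SaturatedWellError",
    "poisson_concentration",
    "merge_wells",
    "quantify_assay",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class SaturatedWellError(ValueError):
    """Every droplet positive: lambda (hence concentration) is undefined."""


@dataclass(frozen=True)
class TargetConcentration:
    """Poisson-corrected concentration of one target.

    ``copies_per_uL = lam / droplet_volume_uL``; ``ci95`` bounds are on the
    same copies/uL scale and always bracket the point estimate.
    """

    target: str
    copies_per_uL: float
    lam: float
    ci95: tuple[float, float]
    n_positive: int
    n_total: int
    droplet_volume_uL: float
    wells_merged: int = 1

    def __post_init__(self) -> None:
        if not self.ci95[0] <= self.copies_per_uL <= self.ci95[1]:
            raise ValueError("CI must bracket the point estimate")
        if self.n_positive > self.n_total:
            raise ValueError("n_positive cannot exceed n_total")


def poisson_concentration(
    n_positive: int,
    n_total: int,
    droplet_volume_uL: float = DEFAULT_DROPLET_VOLUME_UL,
    *,
    target: str = "",
    ci_method: str = "normal",
    wells_merged: int = 1,
) -> TargetConcentration:
    """Point estimate and 95% CI from a positive/total droplet count.

    ``ci_method='normal'`` propagates ``p_hat +/- 1.96*sqrt(p(1-p)/n)``
    through ``-ln(1-p)``; ``'clopper-pearson'`` inverts the exact binomial.
    Raises :class:`SaturatedWellError` when every droplet is positive.
    """
    if droplet_volume_uL <= 0:
        raise ValueError("droplet_volume_uL must be positive")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_positive < 0 or n_positive > n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    if n_positive == n_total:
        raise SaturatedWellError(
            f"all {n_total} droplets positive{' for ' + target if target else ''}: "
            "saturated well, lambda undefined"
        )
    p = n_positive / n_total
    lam = -math.log1p(-p)
    if ci_method == "normal":
        half = _Z95 * math.sqrt(p * (1.0 - p) / n_total)
        p_lo = max(0.0, p - half)
        p_hi = p + half
    elif ci_method == "clopper-pearson":
        p_lo = 0.0 if n_positive == 0 else float(
            stats.beta.ppf(0.025, n_positive, n_total - n_positive + 1)
        )
        p_hi = float(stats.beta.ppf(0.975, n_positive + 1, n_total - n_positive))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lam_lo = -math.log1p(-p_lo)
    lam_hi = math.inf if p_hi >= 1.0 else -math.log1p(-p_hi)
    return TargetConcentration(
        target=target,
        copies_per_uL=lam / droplet_volume_uL,
        lam=lam,
        ci95=(lam_lo / droplet_volume_uL, lam_hi / droplet_volume_uL),
        n_positive=n_positive,
        n_total=n_total,
        droplet_volume_uL=droplet_volume_uL,
        wells_merged=wells_merged,
    )


def merge_wells(
    well_counts: Sequence[tuple[int, int]],
    droplet_volume_uL: float = DEFAULT_DROPLET_VOLUME_UL,
    *,
    target: str = "",
    ci_method: str = "normal",
    volumes: Sequence[float] | None = None,
) -> TargetConcentration:
    """Merged-well estimator: pool positives and totals, then correct.

    All wells must share a droplet volume; pass per-well ``volumes`` to have
    that checked explicitly.
    """
    if not well_counts:
        raise ValueError("need at least one well")
    if volumes is not None:
        if len(volumes) != len(well_counts):
            raise ValueError("one volume per well required")
        if any(not math.isclose(v, volumes[0], rel_tol=1e-9) for v in volumes):
            raise ValueError("wells with differing droplet volumes cannot be merged")
        droplet_volume_uL = volumes[0]
    n_pos = sum(c[0] for c in well_counts)
    n_tot = sum(c[1] for c in well_counts)
    return poisson_concentration(
        n_pos, n_tot, droplet_volume_uL,
        target=target, ci_method=ci_method, wells_merged=len(well_counts),
    )


def quantify_assay(
    ds: DropletSet,
    gates: GateSet,
    assay: AssayDesign,
    droplet_volume_uL: float = DEFAULT_DROPLET_VOLUME_UL,
    *,
    ci_method: str = "normal",
) -> dict[str, TargetConcentration]:
    """Gate a well and Poisson-correct every assay target.

    Saturation surfaces with the offending target's name so an operator can
    dilute and re-run.
    """
    result = call_populations(ds, gates)
    counts = positive_counts(result.counts, assay)
    return {
        t: poisson_concentration(
            n_pos, n_tot, droplet_volume_uL, target=t, ci_method=ci_method
        )
        for t, (n_pos, n_tot) in counts.items()
    }
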