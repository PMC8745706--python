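"""AR copy-number, chromosome-X dosage, and T877A mutation calling.

The biomarker math on top of per-target concentrations:

* AR-Amp-1/T877A:  ``AR CN = (WT + MT) / RPP30 * 2``
* AR-Amp-2:        ``AR CN = (AR-X1 + AR-X2) / (MYM* + TBP) * 2`` where
  ``MYM* = 2 * MYM`` for male samples (X hemizygosity: a normal male genome
  carries one MYM allele, so the raw reading must be doubled to put the
  X-chromosomal reference on a diploid scale; female samples use MYM as read).
* Chromosome X:    ``Chr X CN = 2 * MYM / TBP`` (raw MYM — the normal male
  expectation is then ~1, and the amplification threshold of 2 corresponds to
  a doubling).

Copy numbers are ratios, hence invariant under global rescaling of the input
concentrations.  Amplification is called at CN >= threshold (default 2,
inclusive: the stated threshold itself is a positive call), a conservative
cut sitting well above the healthy-control CN range.  T877A is reported as a
mutant fraction MT/(MT+WT) with a minimum-positive-droplet detection floor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

from .assays import AssayDesign, TargetRole
from .quantify import TargetConcentration

__all__ = [
    "CNResult",
    "MutationCall",
    "ChrXResult",
    "ConcordanceRecord",
    "ar_cn_amp1",
    "ar_cn_amp2",
    "ar_copy_number",
    "chrx_cn",
    "t877a_call",
    "classify_amplification",
    "cross_validate",
    "round_half_up",
    "DEFAULT_AMPLIFICATION_THRESHOLD",
]

DEFAULT_AMPLIFICATION_THRESHOLD = 2.0


def round_half_up(x: float, decimals: int = 0) -> float:
    """Commercial rounding (0.5 always rounds up), as used in reported CN."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify_amplification(
    cn: float, threshold: float = DEFAULT_AMPLIFICATION_THRESHOLD
) -> bool:
    """Amplified iff CN >= threshold (boundary inclusive)."""
    if cn < 0:
        raise ValueError("cn must be non-negative")
    return cn >= threshold


@dataclass(frozen=True)
class CNResult:
    assay_id: str
    ar_ref_ratio: float
    cn: float
    cn_display: float
    amplified: bool
    threshold: float
    sex_used: str


@dataclass(frozen=True)
class MutationCall:
    mutant_copies_per_uL: float
    wildtype_copies_per_uL: float
    mutant_fraction: Optional[float]  # None when MT + WT == 0
    detected: bool
    min_positive_droplets: int


@dataclass(frozen=True)
class ChrXResult:
    chrx_cn: float
    amplified: bool
    threshold: float


@dataclass(frozen=True)
class ConcordanceRecord:
    cn_1: float
    cn_2: float
    amplified_1: bool
    amplified_2: bool
    concordant: bool
    relative_difference: float


def ar_cn_amp1(
    mt: float,
    wt: float,
    rpp30: float,
    *,
    threshold: float = DEFAULT_AMPLIFICATION_THRESHOLD,
    sex: str = "male",
    display_decimals: int = 0,
) -> CNResult:
    """AR CN from the AR-Amp-1/T877A assay: ``(WT + MT) / RPP30 * 2``.

    Inputs are copies/uL.  RPP30 sits on chromosome 10 (two alleles in every
    normal cell), so no sex correction applies.
    """
    if mt < 0 or wt < 0:
        raise ValueError("concentrations must be non-negative")
    if rpp30 <= 0:
        raise ValueError("no reference signal: RPP30 concentration is zero")
    ratio = (wt + mt) / rpp30
    cn = 2.0 * ratio
    return CNResult(
        assay_id="AR-Amp-1/T877A",
        ar_ref_ratio=ratio,
        cn=cn,
        cn_display=round_half_up(cn, display_decimals),
        amplified=classify_amplification(cn, threshold),
        threshold=threshold,
        sex_used=sex,
    )


def ar_cn_amp2(
    x1: float,
    x2: float,
    mym_raw: float,
    tbp: float,
    sex: str,
    *,
    threshold: float = DEFAULT_AMPLIFICATION_THRESHOLD,
    display_decimals: int = 0,
) -> CNResult:
    """AR CN from AR-Amp-2: ``(AR-X1 + AR-X2) / (MYM* + TBP) * 2``.

    ``mym_raw`` is the MYM reading as measured; it is doubled internally for
    male samples (X hemizygosity) to give MYM*.
    """
    if min(x1, x2, mym_raw, tbp) < 0:
        raise ValueError("concentrations must be non-negative")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    mym_star = 2.0 * mym_raw if sex == "male" else mym_raw
    denom = mym_star + tbp
    if denom <= 0:
        raise ValueError("no reference signal: MYM* + TBP is zero")
    ratio = (x1 + x2) / denom
    cn = 2.0 * ratio
    return CNResult(
        assay_id="AR-Amp-2",
        ar_ref_ratio=ratio,
        cn=cn,
        cn_display=round_half_up(cn, display_decimals),
        amplified=classify_amplification(cn, threshold),
        threshold=threshold,
        sex_used=sex,
    )


def ar_copy_number(
    assay: AssayDesign,
    concentrations: Mapping[str, TargetConcentration],
    sex: str,
    *,
    threshold: float = DEFAULT_AMPLIFICATION_THRESHOLD,
) -> CNResult:
    """Generic diploid-normalised CN for any assay design.

    Numerator: summed concentrations of all non-reference targets.
    Denominator: each reference rescaled to a diploid scale by
    ``2 / alleles_per_normal_cell[sex]`` (this reproduces the MYM* doubling
    for male samples and leaves autosomal references untouched).
    """
    num = sum(
        concentrations[t.name].copies_per_uL
        for t in assay.targets
        if t.role is not TargetRole.REFERENCE
    )
    denom = sum(
        concentrations[t.name].copies_per_uL * (2.0 / t.alleles(sex))
        for t in assay.references
    )
    if denom <= 0:
        raise ValueError(f"no reference signal in assay {assay.assay_id!r}")
    ratio = num / denom
    cn = 2.0 * ratio
    return CNResult(
        assay_id=assay.assay_id,
        ar_ref_ratio=ratio,
        cn=cn,
        cn_display=round_half_up(cn, 0),
        amplified=classify_amplification(cn, threshold),
        threshold=threshold,
        sex_used=sex,
    )


def chrx_cn(
    mym_raw: float,
    tbp: float,
    sex: str = "male",
    *,
    threshold: float = DEFAULT_AMPLIFICATION_THRESHOLD,
) -> ChrXResult:
    """Chromosome-X dosage: ``Chr X CN = 2 * MYM / TBP`` (raw MYM).

    Calibrated for male samples (normal male ~1; threshold 2 = doubling).
    The formula has no established female interpretation; female input is
    accepted with a warning.
    """
    if mym_raw < 0:
        raise ValueError("MYM concentration must be non-negative")
    if tbp <= 0:
        raise ValueError("no reference signal: TBP concentration is zero")
    if sex == "female":
        warnings.warn(
            "Chr X CN is calibrated for male samples; female value is "
            "reported as computed but has no validated interpretation",
            stacklevel=2,
        )
    cn = 2.0 * mym_raw / tbp
    return ChrXResult(
        chrx_cn=cn,
        amplified=classify_amplification(cn, threshold),
        threshold=threshold,
    )


def t877a_call(
    mt: TargetConcentration,
    wt: TargetConcentration,
    min_positive_droplets: int = 3,
) -> MutationCall:
    """Mutant-fraction and detection call for T877A.

    Detection requires at least ``min_positive_droplets`` mutant-positive
    droplets — a pragmatic floor against isolated false-positive events in
    lieu of a formal limit-of-blank.
    """
    total = mt.copies_per_uL + wt.copies_per_uL
    fraction = mt.copies_per_uL / total if total > 0 else None
    return MutationCall(
        mutant_copies_per_uL=mt.copies_per_uL,
        wildtype_copies_per_uL=wt.copies_per_uL,
        mutant_fraction=fraction,
        detected=mt.n_positive >= min_positive_droplets,
        min_positive_droplets=min_positive_droplets,
    )


def cross_validate(cn1: CNResult, cn2: CNResult) -> ConcordanceRecord:
    """Concordance of the two assays' CN calls on one sample.

    Discordant amplification flags mark the sample for review — the two
    assays are designed to confirm each other, so disagreement is an anomaly
    to surface, not to resolve silently.
    """
    mean = (cn1.cn + cn2.cn) / 2.0
    rel = abs(cn1.cn - cn2.cn) / mean if mean > 0 else 0.0
    return ConcordanceRecord(
        cn_1=cn1.cn,
        cn_2=cn2.cn,
        amplified_1=cn1.amplified,
        amplified_2=cn2.amplified,
        concordant=cn1.amplified == cn2.amplified,
        relative_difference=rel,
    )
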