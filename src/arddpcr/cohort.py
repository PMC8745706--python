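"""Cohort-level statistics for AR amplification studies.

Covers the statistical surface of a liquid-biopsy biomarker cohort: the
healthy-control CN range that anchors the amplification threshold, exact
2x2 association tests between amplification status and treatment history,
rank-based group comparison, and cross-assay correlation.

Conventions
-----------
* Fisher's exact two-sided p is the sum of hypergeometric point
  probabilities no larger than the observed table's (fixed margins) — the
  convention of scipy and of common biostatistics software.
* Mann-Whitney uses the exact null distribution for small samples without
  ties and the tie-corrected normal approximation with continuity correction
  otherwise.
* SEM uses the sample standard deviation (n-1 denominator).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .cncall import DEFAULT_AMPLIFICATION_THRESHOLD, classify_amplification

__all__ = [
    "CohortRecord",
    "ContingencyTable2x2",
    "Table4Result",
    "healthy_threshold_summary",
    "fisher_exact_2x2",
    "mann_whitney",
    "pearson_correlation",
    "build_table4",
]


@dataclass(frozen=True)
class CohortRecord:
    """Per-sample summary feeding cohort statistics."""

    sample_id: str
    sex: str
    disease_state: str  # "HSPC" | "CRPC" | "healthy"
    cn_assay1: float
    cn_assay2: float
    t877a_detected: bool = False
    chrx_cn: Optional[float] = None
    chemo: Optional[bool] = None
    enz_abi: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.disease_state not in ("HSPC", "CRPC", "healthy"):
            raise ValueError(f"unknown disease_state {self.disease_state!r}")
        if self.cn_assay1 < 0 or self.cn_assay2 < 0:
            raise ValueError("CN values must be non-negative")
        if self.disease_state == "healthy" and (self.chemo or self.enz_abi):
            raise ValueError("healthy records cannot carry treatment flags")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: high / normal AR CN; columns: treatment + / -."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def healthy_threshold_summary(healthy_cns: Sequence[float]) -> dict:
    """Summarise healthy-control CN and suggest an amplification threshold.

    The suggested threshold is conservative: never below 2, and never below
    the healthy maximum (rounded up to one decimal), so no healthy control
    would be called amplified.
    """
    values = np.asarray(healthy_cns, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two healthy-control CN values")
    mx = float(values.max())
    return {
        "n": int(values.size),
        "min": float(values.min()),
        "max": mx,
        "mean": float(values.mean()),
        "sem": float(values.std(ddof=1) / math.sqrt(values.size)),
        "suggested_threshold": max(2.0, math.ceil(mx * 10.0) / 10.0),
    }


def fisher_exact_2x2(t: ContingencyTable2x2) -> dict:
    """Exact two-sided Fisher test and sample odds ratio ``(a*d)/(b*c)``.

    The odds ratio is ``inf`` when only ``b*c`` vanishes and ``nan`` when
    both products vanish.
    """
    res = stats.fisher_exact(t.as_array(), alternative="two-sided")
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        odds = math.nan if ad == 0 else math.inf
    else:
        odds = ad / bc
    return {"p_two_sided": float(res.pvalue), "odds_ratio": odds}


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney U test (U reported for ``group_a``).

    Exact null distribution when ``min(n_a, n_b) <= 8`` and no ties span the
    two groups; tie-corrected normal approximation with continuity correction
    otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return {"U": float(res.statistic), "p_two_sided": float(res.pvalue), "method": method}


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> dict:
    """Product-moment correlation with a t-distribution p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least three paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return {"r": float(res.statistic), "p_two_sided": float(res.pvalue)}


@dataclass(frozen=True)
class Table4Result:
    table: ContingencyTable2x2
    grouping: str
    n_included: int
    n_excluded_missing: int
    n_discordant: int
    discordant_ids: tuple[str, ...] = ()


_GROUPINGS = ("chemo", "enz_abi", "chemo_and_enz_abi")


def build_table4(
    cohort: Iterable[CohortRecord],
    grouping: str,
    *,
    threshold: float = DEFAULT_AMPLIFICATION_THRESHOLD,
) -> Table4Result:
    """Amplification-vs-treatment 2x2 table over patient records.

    Rows are amplified vs normal AR CN, calling a sample amplified only when
    both assays agree (cn_assay1 call with cn_assay2 concordance); samples
    where the assays disagree are excluded and reported as discordant rather
    than silently resolved.  Columns follow ``grouping``: prior chemotherapy,
    prior second-generation ADT (enzalutamide/abiraterone), or both-vs-others.
    Records lacking treatment flags are excluded with a warning and counted.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"grouping must be one of {_GROUPINGS}")
    a = b = c = d = 0
    n_missing = 0
    discordant: list[str] = []
    n_included = 0
    for rec in cohort:
        if rec.disease_state == "healthy":
            continue
        if rec.chemo is None or rec.enz_abi is None:
            n_missing += 1
            continue
        amp1 = classify_amplification(rec.cn_assay1, threshold)
        amp2 = classify_amplification(rec.cn_assay2, threshold)
        if amp1 != amp2:
            discordant.append(rec.sample_id)
            continue
        if grouping == "chemo":
            in_group = rec.chemo
        elif grouping == "enz_abi":
            in_group = rec.enz_abi
        else:
            in_group = rec.chemo and rec.enz_abi
        n_included += 1
        if amp1:
            a, b = (a + 1, b) if in_group else (a, b + 1)
        else:
            c, d = (c + 1, d) if in_group else (c, d + 1)
    if n_missing:
        warnings.warn(
            f"{n_missing} record(s) excluded for missing treatment information",
            stacklevel=2,
        )
    if n_included == 0:
        raise ValueError("no usable patient records for the contingency table")
    return Table4Result(
        table=ContingencyTable2x2(a, b, c, d),
        grouping=grouping,
        n_included=n_included,
        n_excluded_missing=n_missing,
        n_discordant=len(discordant),
        discordant_ids=tuple(discordant),
    )
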