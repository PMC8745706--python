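"""Worked-example data: published cell-line characterisation of both assays.

Per-gene concentrations (copies/uL of reaction) measured on gDNA from PBMCs
and prostate/breast cancer cell lines, together with the reported ratio / CN
values, and the treatment-association contingency tables of the patient
cohort.  These serve as fixed arithmetic fixtures for the CN formulas and the
exact tests; concentrations are inputs, the ratio/CN columns are the reported
outputs to reproduce.

Notes: the AR-Amp-2 table reports the MYM* column (already doubled for male
samples); ``mym_star_is_raw`` marks the female line where MYM* equals the raw
reading.  Reported ratios/CN were rounded by the original analysts from
unrounded raw readings, so recomputation from the printed concentrations can
differ in the last printed digit.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AMP1_PANEL", "AMP2_PANEL", "TREATMENT_TABLES", "CHRX_PATIENT_EXAMPLE"]


@dataclass(frozen=True)
class Amp1Row:
    sample: str
    mt: float          # T877A copies/uL
    wt: float
    rpp30: float
    reported_ratio: float
    reported_cn: float
    mixture: bool      # mixture rows report CN at one decimal


AMP1_PANEL: tuple[Amp1Row, ...] = (
    Amp1Row("PBMC-M", 0.0, 45.4, 90.0, 0.51, 1.0, False),
    Amp1Row("PBMC-F", 0.0, 81.0, 77.0, 1.05, 2.0, False),
    Amp1Row("MFM-223", 0.0, 198.0, 51.5, 3.84, 8.0, False),
    Amp1Row("VCaP", 0.0, 721.0, 52.5, 13.73, 28.0, False),
    Amp1Row("LNCaP", 114.0, 0.0, 228.0, 0.50, 1.0, False),
    Amp1Row("LNCaP + PBMC-M (2:1)", 30.1, 16.2, 89.3, 0.52, 1.0, True),
    Amp1Row("LNCaP + MFM-223 (2:1)", 29.0, 60.7, 68.7, 1.31, 2.6, True),
    Amp1Row("LNCaP + VCaP (2:1)", 20.4, 191.0, 61.7, 3.43, 6.9, True),
)


@dataclass(frozen=True)
class Amp2Row:
    sample: str
    x1: float
    x2: float
    tbp: float
    mym_star: float    # as reported: doubled for male samples
    sex: str
    reported_cn: float


AMP2_PANEL: tuple[Amp2Row, ...] = (
    Amp2Row("PBMC-M", 45.9, 42.0, 87.0, 84.6, "male", 1.0),
    Amp2Row("PBMC-F", 73.0, 72.6, 73.1, 75.0, "female", 2.0),
    Amp2Row("MFM-223", 173.0, 176.0, 46.3, 51.8, "female", 7.0),
    Amp2Row("VCaP", 696.0, 709.0, 54.0, 69.0, "male", 23.0),
    Amp2Row("LNCaP", 97.0, 100.0, 189.0, 194.0, "male", 1.0),
)


def amp2_raw_mym(row: Amp2Row) -> float:
    """Undo the MYM* doubling to recover the raw MYM reading."""
    return row.mym_star / 2.0 if row.sex == "male" else row.mym_star


#: Amplification-status vs treatment 2x2 tables (rows: high / normal AR CN;
#: columns: treatment + / -) with the reported two-sided Fisher p values.
TREATMENT_TABLES: dict[str, dict] = {
    "chemo": {"table": ((5, 4), (7, 14)), "reported_p": 0.42},
    "enz_abi": {"table": ((4, 5), (10, 11)), "reported_p": 0.99},
    "chemo_and_enz_abi": {"table": ((2, 7), (2, 19)), "reported_p": 0.56},
}

#: Patient with a large chromosome-X gain: MYM elevated 2.15-fold over TBP on
#: the diploid scale, giving Chr X CN = 4.30.
CHRX_PATIENT_EXAMPLE = {"mym_over_tbp": 2.15, "reported_chrx_cn": 4.30}
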