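"""End-to-end composition: droplets -> concentrations -> biomarker calls.

Also provides the synthetic patient cohort generator used by the worked
analyses: a prostate-cancer-style cohort (healthy controls, hormone-sensitive
and castration-resistant patients, a minority of AR-amplified samples, rare
T877A carriers, one chromosome-X-amplified case) pushed through the full
simulate -> gate -> quantify -> call pipeline for both assays, yielding
per-sample records plus the generating ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .assays import AssayDesign, builtin_assay
from .cncall import (
    DEFAULT_AMPLIFICATION_THRESHOLD,
    ChrXResult,
    CNResult,
    MutationCall,
    ar_cn_amp1,
    ar_cn_amp2,
    ar_copy_number,
    chrx_cn,
    t877a_call,
)
from .cohort import CohortRecord
from .gating import GateSet, derive_gates
from .quantify import TargetConcentration, quantify_assay
from .simulate import (
    DEFAULT_DROPLET_VOLUME_UL,
    DEFAULT_N_DROPLETS,
    AmplitudeModel,
    DropletSet,
    GenomeProfile,
    simulate_controls,
    simulate_sample,
)

__all__ = ["SampleAssayResult", "analyze_sample", "CohortSimulation", "simulate_cohort"]


@dataclass(frozen=True)
class SampleAssayResult:
    """Everything one assay says about one sample."""

    sample_id: str
    assay_id: str
    concentrations: Mapping[str, TargetConcentration]
    cn: CNResult
    mutation: Optional[MutationCall] = None
    chrx: Optional[ChrXResult] = None


def analyze_sample(
    assay: AssayDesign,
    ds: DropletSet,
    gates: GateSet,
    *,
    sex: str,
    droplet_volume_uL: float = DEFAULT_DROPLET_VOLUME_UL,
    threshold: float = DEFAULT_AMPLIFICATION_THRESHOLD,
    min_mutant_droplets: int = 3,
) -> SampleAssayResult:
    """Gate, quantify and call one sample's well under one assay.

    The built-in assays get their published CN formulas (including the MYM*
    hemizygosity rule and, for AR-Amp-2, the Chr X dosage); any other design
    falls back to the generic allele-count-normalised ratio.
    """
    conc = quantify_assay(ds, gates, assay, droplet_volume_uL)
    mutation = None
    chrx = None
    if assay.assay_id == "AR-Amp-1/T877A":
        cn = ar_cn_amp1(
            conc["MT"].copies_per_uL, conc["WT"].copies_per_uL,
            conc["RPP30"].copies_per_uL, threshold=threshold, sex=sex,
        )
        mutation = t877a_call(conc["MT"], conc["WT"], min_mutant_droplets)
    elif assay.assay_id == "AR-Amp-2":
        cn = ar_cn_amp2(
            conc["AR-X1"].copies_per_uL, conc["AR-X2"].copies_per_uL,
            conc["MYM"].copies_per_uL, conc["TBP"].copies_per_uL,
            sex, threshold=threshold,
        )
        chrx = chrx_cn(conc["MYM"].copies_per_uL, conc["TBP"].copies_per_uL, sex,
                       threshold=threshold)
    else:
        cn = ar_copy_number(assay, conc, sex, threshold=threshold)
    return SampleAssayResult(
        sample_id=ds.sample_id, assay_id=assay.assay_id,
        concentrations=conc, cn=cn, mutation=mutation, chrx=chrx,
    )


# ---------------------------------------------------------------------------
# synthetic cohort

@dataclass(frozen=True)
class CohortSimulation:
    records: list[CohortRecord]
    true_cn: Mapping[str, float]
    true_t877a: frozenset[str]
    chrx_sample: Optional[str]


# Treatment-history layout for the flagged CRPC patients, laid out so that the
# chemo / second-generation-ADT margins of the association analysis are fixed
# by design: (n, chemo, enz_abi) blocks for amplified and normal-CN patients.
_AMPLIFIED_TREATMENT_BLOCKS = ((2, True, True), (3, True, False), (2, False, True), (2, False, False))
_NORMAL_TREATMENT_BLOCKS = ((2, True, True), (5, True, False), (8, False, True), (6, False, False))


def simulate_cohort(
    seed: int,
    *,
    n_healthy: int = 7,
    n_hspc: int = 16,
    n_crpc: int = 31,
    n_amplified: int = 9,
    n_t877a: int = 2,
    amplified_cn_range: tuple[float, float] = (4.0, 48.0),
    t877a_fraction: float = 0.3,
    chrx_gain: Optional[float] = 4.3,
    n_droplets: int = DEFAULT_N_DROPLETS,
    model: AmplitudeModel | None = None,
    threshold: float = DEFAULT_AMPLIFICATION_THRESHOLD,
) -> CohortSimulation:
    """Simulate an advanced-prostate-cancer cohort through both assays.

    Study conditions: ``n_healthy`` male healthy controls around CN 1,
    ``n_hspc`` hormone-sensitive and ``n_crpc`` castration-resistant patients,
    of whom ``n_amplified`` CRPC patients carry true AR CN drawn log-uniformly
    over ``amplified_cn_range``; the rest sit in the healthy-like band.
    ``n_t877a`` HSPC patients carry the mutation at ``t877a_fraction`` of
    their AR copies.  The highest-CN patient additionally carries a
    chromosome-X gain placing Chr X CN at ``chrx_gain`` (pass ``None`` for a
    cohort whose two assays share the true CN exactly — the X gain inflates
    the MYM reference and therefore legitimately depresses the AR-Amp-2 CN of
    that one patient).  One flagged-missing
    CRPC patient exercises the missing-treatment-information path; the others
    get treatment flags in fixed blocks.  All samples are male (prostate
    cohort).  Per-sample cfDNA genome concentration is log-normal around ~35
    genome equivalents per uL of reaction.
    """
    rng = np.random.default_rng(seed)
    model = model or AmplitudeModel()
    amp1 = builtin_assay("AR-Amp-1/T877A")
    amp2 = builtin_assay("AR-Amp-2")
    gates = {
        a.assay_id: derive_gates(
            simulate_controls(a, seed=int(rng.integers(2**31 - 1)), model=model), a
        )
        for a in (amp1, amp2)
    }

    # --- draw per-sample ground truth -------------------------------------
    samples: list[dict] = []
    for i in range(n_healthy):
        samples.append({
            "id": f"HC{i+1:02d}", "state": "healthy",
            "cn": float(np.clip(rng.normal(1.08, 0.16), 0.6, 1.7)),
            "mt_frac": 0.0, "mym": None,
        })
    for i in range(n_hspc):
        samples.append({
            "id": f"HS{i+1:02d}", "state": "HSPC",
            "cn": float(np.clip(rng.normal(1.15, 0.22), 0.7, 1.92)),
            "mt_frac": t877a_fraction if i < n_t877a else 0.0, "mym": None,
        })
    lo, hi = amplified_cn_range
    amplified_cns = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_amplified))
    for i in range(n_crpc):
        amplified = i < n_amplified
        samples.append({
            "id": f"CR{i+1:02d}", "state": "CRPC",
            "cn": float(amplified_cns[i]) if amplified
            else float(np.clip(rng.normal(1.15, 0.22), 0.7, 1.92)),
            "mt_frac": 0.0, "mym": None, "amplified": amplified,
        })
    chrx_sample = None
    crpc = [s for s in samples if s["state"] == "CRPC"]
    amped = [s for s in crpc if s.get("amplified")]
    if amped and chrx_gain is not None:
        top = max(amped, key=lambda s: s["cn"])
        top["mym"] = chrx_gain  # Chr X CN = 2*MYM/TBP = chrx_gain with TBP=2
        chrx_sample = top["id"]

    # --- treatment flags (CRPC only; one record left missing) -------------
    def _assign(blocks, group):
        it = iter(group)
        for n, chemo, enz in blocks:
            for _ in range(n):
                try:
                    s = next(it)
                except StopIteration:
                    return
                s["chemo"], s["enz_abi"] = chemo, enz

    normals = [s for s in crpc if not s.get("amplified")]
    if normals:
        normals[-1]["chemo"] = normals[-1]["enz_abi"] = None  # missing info
    _assign(_AMPLIFIED_TREATMENT_BLOCKS, amped)
    _assign(_NORMAL_TREATMENT_BLOCKS, normals[:-1] if normals else [])

    # --- run every sample through both assays -----------------------------
    records: list[CohortRecord] = []
    for s in samples:
        ge = float(np.clip(rng.lognormal(np.log(35.0), 0.4), 10.0, 150.0))
        profile = GenomeProfile(
            {
                "MT": s["mt_frac"] * s["cn"],
                "WT": (1.0 - s["mt_frac"]) * s["cn"],
                "RPP30": 2.0,
                "AR-X1": s["cn"],
                "AR-X2": s["cn"],
                "MYM": s["mym"] if s["mym"] is not None else 1.0,
                "TBP": 2.0,
            },
            sex="male",
        )
        results = {}
        for assay in (amp1, amp2):
            ds = simulate_sample(
                assay, profile, ge,
                seed=int(rng.integers(2**31 - 1)),
                n_droplets=n_droplets, model=model,
                well_id=f"{s['id']}-{assay.assay_id[:6]}", sample_id=s["id"],
            )
            results[assay.assay_id] = analyze_sample(
                assay, ds, gates[assay.assay_id], sex="male", threshold=threshold
            )
        r1 = results["AR-Amp-1/T877A"]
        r2 = results["AR-Amp-2"]
        records.append(CohortRecord(
            sample_id=s["id"],
            sex="male",
            disease_state=s["state"],
            cn_assay1=r1.cn.cn,
            cn_assay2=r2.cn.cn,
            t877a_detected=bool(r1.mutation and r1.mutation.detected),
            chrx_cn=r2.chrx.chrx_cn if r2.chrx else None,
            chemo=s.get("chemo"),
            enz_abi=s.get("enz_abi"),
        ))
    return CohortSimulation(
        records=records,
        true_cn={s["id"]: s["cn"] for s in samples},
        true_t877a=frozenset(s["id"] for s in samples if s["mt_frac"] > 0),
        chrx_sample=chrx_sample,
    )
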