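"""Simulate the patient cohort through the full pipeline.

A 47-patient advanced-prostate-cancer cohort (16 HSPC + 31 CRPC, of whom 9
CRPC carry true AR amplification between 4- and 48-fold, two HSPC patients
carry T877A, one amplified patient a large Chr X gain) plus 7 healthy male
controls, every sample measured by both assays on simulated 20,000-droplet
wells.  Writes per-sample calls to results/cohort_calls.tsv along with the
generating truth for auditing.
"""

from pathlib import Path

import pandas as pd

from arddpcr.pipeline import simulate_cohort

SEED = 47
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    sim = simulate_cohort(SEED)
    rows = []
    for r in sim.records:
        rows.append({
            "sample_id": r.sample_id, "sex": r.sex, "disease_state": r.disease_state,
            "cn_assay1": round(r.cn_assay1, 3), "cn_assay2": round(r.cn_assay2, 3),
            "t877a_detected": r.t877a_detected,
            "chrx_cn": round(r.chrx_cn, 3) if r.chrx_cn is not None else "",
            "chemo": "" if r.chemo is None else r.chemo,
            "enz_abi": "" if r.enz_abi is None else r.enz_abi,
            "true_cn": round(sim.true_cn[r.sample_id], 3),
            "true_t877a": r.sample_id in sim.true_t877a,
        })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "cohort_calls.tsv", sep="\t", index=False)
    n_amp = int(((df["cn_assay1"] >= 2) & (df["cn_assay2"] >= 2)
                 & (df["disease_state"] != "healthy")).sum())
    print(f"cohort: {len(df)} samples; amplified called in {n_amp} patients; "
          f"T877A detected in {int(df['t877a_detected'].sum())}; "
          f"Chr X gain sample: {sim.chrx_sample}")
    print(f"-> {RESULTS / 'cohort_calls.tsv'}")


if __name__ == "__main__":
    main()
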