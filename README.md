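# arddpcr

Multiplexed droplet digital PCR (ddPCR) analysis of **androgen receptor (AR)
copy number** and the **T877A point mutation** from plasma cell-free DNA
(cfDNA) — a liquid-biopsy biomarker pipeline for advanced prostate cancer,
where AR amplification marks castration resistance and T877A converts
anti-androgens into agonists.

The package takes droplet-level two-channel fluorescence amplitudes (QX200
style: ~20,000 droplets of ~0.85 nL per well, FAM on channel 1, HEX on
channel 2) and carries them through every analysis stage:

1. **Assay registry** — two built-in amplitude-multiplexed assays as data:
   *AR-Amp-1/T877A* (MT, WT, RPP30) and *AR-Amp-2* (AR-X1, AR-X2, MYM, TBP),
   plus arbitrary user designs.
2. **Synthetic droplets** — a simulator with Poisson template partitioning,
   additive combination-droplet amplitudes, Gaussian noise and optional rain,
   producing ground-truth labels so every downstream stage is testable.
3. **Gating** — control-derived per-channel band cuts (midpoints between
   fitted band centers, full 2^k combination enumeration), droplet →
   population labels, per-target positive counts.
4. **Quantification** — Poisson correction λ = −ln(1 − p), concentration
   λ/V copies/µL with 95% CIs, merged-well estimation.
5. **Copy-number calling** — the biomarker math:

   ```
   AR-Amp-1/T877A:  AR CN = (WT + MT) / RPP30 × 2
   AR-Amp-2:        AR CN = (AR-X1 + AR-X2) / (MYM* + TBP) × 2
                    MYM*  = 2 × MYM for male samples (X hemizygosity)
   Chromosome X:    Chr X CN = 2 × MYM / TBP
   ```

   with amplification called at CN ≥ 2 (inclusive), T877A as mutant fraction
   MT/(MT+WT) with a ≥3-droplet detection floor, and cross-assay concordance.
6. **Cohort statistics** — healthy-control threshold summaries, exact
   two-sided Fisher tests of amplification vs treatment history,
   Mann–Whitney group comparison, cross-assay Pearson correlation.

## Worked example

```python
from arddpcr import ar_cn_amp1, ar_cn_amp2

# published cell-line concentrations (copies/µL): MFM-223 under AR-Amp-1
res = ar_cn_amp1(mt=0.0, wt=198.0, rpp30=51.5)
print(round(res.ar_ref_ratio, 2), res.cn_display, res.amplified)
# 3.84 8.0 True

# VCaP under AR-Amp-2: reported MYM* = 69 for a male sample -> raw MYM 34.5
res = ar_cn_amp2(x1=696.0, x2=709.0, mym_raw=34.5, tbp=54.0, sex="male")
print(res.cn_display, res.amplified)
# 23.0 True
```

The AR:RPP30 ratio 3.84 says MFM-223 carries ~3.84 AR copies per RPP30
copy; doubling puts it on the diploid scale (CN 8, amplified). VCaP reads
CN 23 under AR-Amp-2 — the hemizygosity doubling of MYM keeps a normal male
genome at CN 1 on the same scale.

End-to-end on synthetic droplets:

```python
from arddpcr import builtin_assay, derive_gates, simulate_sample
from arddpcr.simulate import GENOME_PROFILES, simulate_controls
from arddpcr.pipeline import analyze_sample

assay = builtin_assay("AR-Amp-1/T877A")
gates = derive_gates(simulate_controls(assay, seed=101), assay)
well = simulate_sample(assay, GENOME_PROFILES["male_normal"], 40.0, seed=11)
print(round(analyze_sample(assay, well, gates, sex="male").cn.cn, 2))
# 0.95
```

## Analysis scripts

The numbered drivers under `analysis/` reproduce the study's analyses on
synthetic data (droplet CSVs go to `scratch/`, tables to `results/`):

| script | what it does |
|---|---|
| `01_simulate_cell_line_panel.py` | simulate the cell-line panel + controls, both assays |
| `02_gate_and_quantify_panel.py`  | derive gates, quantify every panel well |
| `03_copy_number_calls.py`        | CN / T877A / Chr X calls, cross-assay concordance |
| `04_simulate_cohort.py`          | 47-patient cohort + healthy controls through the pipeline |
| `05_cohort_statistics.py`        | healthy range, Mann–Whitney, Pearson r, Fisher tables |

A `arddpcr` console command exposes the same stages as subcommands
(`simulate`, `gate`, `quantify`, `cn`, `cohort`) for file-based runs.

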