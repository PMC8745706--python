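import dataclasses

import numpy as np
import pytest

from arddpcr.assays import AssayDesign, Channel, TargetDef, TargetRole
from arddpcr.gating import (
    GateSet,
    InseparableBandsError,
    InsufficientControlsError,
    PopulationCounts,
    call_populations,
    derive_gates,
    manual_gates,
    positive_counts,
)
from arddpcr.simulate import AmplitudeModel, WellSpec, simulate_controls, simulate_well


class TestDeriveGates:
    def test_band_structure_amp1(self, gates1):
        # CH1 carries only MT: 2 bands; CH2 carries WT and RPP30: 4 bands
        # (negative, WT, RPP30, WT+RPP30) by additive enumeration
        assert [set(s) for s in gates1.band_targets[Channel.CH1_FAM]] == [set(), {"MT"}]
        assert [set(s) for s in gates1.band_targets[Channel.CH2_HEX]] == [
            set(), {"WT"}, {"RPP30"}, {"WT", "RPP30"}]

    def test_full_population_grid_amp2(self, gates2, amp2):
        # 4 bands per channel -> all 16 target combinations reachable
        labels = {
            gates2.label_of(i, j)
            for i in range(len(gates2.band_targets[Channel.CH1_FAM]))
            for j in range(len(gates2.band_targets[Channel.CH2_HEX]))
        }
        assert len(labels) == 16

    def test_centers_match_truth_cluster_means(self, amp1, model):
        # oracle: per-channel means of the truth-labelled control clusters
        controls = simulate_controls(amp1, seed=31, model=model)
        gates = derive_gates(controls, amp1)
        ch2 = controls.ch2
        neg = np.array([not label for label in controls.truth])
        wt = np.array([label == {"WT"} for label in controls.truth])
        centers = gates.band_centers[Channel.CH2_HEX]
        assert centers[0] == pytest.approx(ch2[neg].mean(), abs=1e-9)
        assert centers[1] == pytest.approx(ch2[wt].mean(), abs=1e-9)

    def test_kmeans_path_matches_truth_path(self, amp1, model):
        controls = simulate_controls(amp1, seed=57, model=model)
        g_truth = derive_gates(controls, amp1)
        blind = dataclasses.replace(controls)
        blind.truth = None
        g_kmeans = derive_gates(blind, amp1)
        for ch in Channel:
            np.testing.assert_allclose(
                g_kmeans.cutpoints[ch], g_truth.cutpoints[ch],
                atol=0.2 * min(model.noise_sd),
            )

    def test_single_population_controls_rejected(self, amp1, model):
        only_neg = simulate_well(
            amp1, WellSpec({}, n_droplets=2000, seed=1), model,
        )
        with pytest.raises(InsufficientControlsError):
            derive_gates(only_neg, amp1)

    def test_inseparable_bands_rejected(self, model):
        crowded = AssayDesign("crowded", (
            TargetDef("A", Channel.CH1_FAM, 200.0, TargetRole.GENE_TARGET, "1",
                      {"male": 2, "female": 2}),
            TargetDef("R", Channel.CH2_HEX, 3000.0, TargetRole.REFERENCE, "1",
                      {"male": 2, "female": 2}),
        ))
        controls = simulate_controls(crowded, seed=2, model=model)  # noise sd 120
        with pytest.raises(InseparableBandsError, match="CH1"):
            derive_gates(controls, crowded)


class TestCallPopulations:
    def test_clean_well_label_accuracy(self, amp1, gates1, model):
        ds = simulate_well(
            amp1, WellSpec({"MT": 120.0, "WT": 250.0, "RPP30": 160.0}, seed=77), model
        )
        res = call_populations(ds, gates1)
        accuracy = np.mean([got == want for got, want in zip(res.labels, ds.truth)])
        assert accuracy >= 0.995

    def test_empty_well_all_negative(self, amp1, gates1, model):
        ds = simulate_well(amp1, WellSpec({}, n_droplets=3000, seed=5), model)
        res = call_populations(ds, gates1)
        assert res.counts.get(frozenset()) == 3000

    def test_single_target_control_stays_single(self, amp1, gates1, model):
        ds = simulate_well(amp1, WellSpec({"RPP30": 300.0}, seed=8), model)
        res = call_populations(ds, gates1)
        for label, count in res.counts.counts.items():
            if label - {"RPP30"}:
                assert count == 0, f"spurious population {set(label)}"

    def test_conservation_across_seeds(self, amp1, gates1, model):
        for seed in range(5):
            ds = simulate_well(
                amp1, WellSpec({"WT": 400.0, "RPP30": 200.0}, n_droplets=7000, seed=seed),
                model,
            )
            res = call_populations(ds, gates1)
            assert sum(res.counts.counts.values()) == 7000
            assert len(res.labels) == 7000

    def test_unmapped_cell_flagged_to_nearest(self, amp1, gates1, model):
        # manual gates mapping only the negative and MT cells: droplets in any
        # other cell are flagged and pulled to the nearest mapped center
        gates = manual_gates(
            cutpoints={ch: gates1.cutpoints[ch] for ch in Channel},
            band_targets={ch: gates1.band_targets[ch] for ch in Channel},
            band_centers={ch: gates1.band_centers[ch] for ch in Channel},
            explicit_map={(0, 0): frozenset(), (1, 0): frozenset({"MT"})},
        )
        ds = simulate_well(amp1, WellSpec({"WT": 500.0}, n_droplets=2000, seed=3), model)
        res = call_populations(ds, gates)
        n_wt_truth = sum("WT" in label for label in ds.truth)
        assert res.flagged.sum() >= 0.9 * n_wt_truth
        assert sum(res.counts.counts.values()) == 2000  # flagged stay in totals


class TestPositiveCounts:
    def test_combination_droplets_count_once_per_member(self, amp1):
        pc = PopulationCounts(
            counts={
                frozenset(): 100,
                frozenset({"WT"}): 50,
                frozenset({"WT", "RPP30"}): 10,
                frozenset({"RPP30"}): 40,
            },
            n_total=200,
        )
        counts = positive_counts(pc, amp1)
        assert counts["WT"] == (60, 200)
        assert counts["RPP30"] == (50, 200)
        assert counts["MT"] == (0, 200)

    def test_all_negative(self, amp1):
        pc = PopulationCounts(counts={frozenset(): 500}, n_total=500)
        assert all(v == (0, 500) for v in positive_counts(pc, amp1).values())

    def test_monotone_in_added_droplets(self, amp1):
        base = {frozenset(): 10, frozenset({"WT"}): 5}
        before = positive_counts(PopulationCounts(base, 15), amp1)["WT"][0]
        grown = dict(base)
        grown[frozenset({"WT", "MT"})] = 1
        after = positive_counts(PopulationCounts(grown, 16), amp1)["WT"][0]
        assert after == before + 1

    def test_counts_must_sum(self):
        with pytest.raises(ValueError):
            PopulationCounts(counts={frozenset(): 5}, n_total=6)

    def test_per_target_positives_match_truth(self, amp1, gates1, model):
        ds = simulate_well(amp1, WellSpec({"WT": 300.0, "MT": 100.0}, seed=13), model)
        res = call_populations(ds, gates1)
        counts = positive_counts(res.counts, amp1)
        for t in ("WT", "MT"):
            truth_pos = sum(t in label for label in ds.truth)
            assert abs(counts[t][0] - truth_pos) <= 0.005 * len(ds)
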