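import math

import numpy as np
import pytest
from scipy import stats

from arddpcr.simulate import (
    AmplitudeModel,
    GENOME_PROFILES,
    WellSpec,
    mix_profiles,
    read_ground_truth,
    simulate_sample,
    simulate_well,
    write_ground_truth,
)

VOL = 0.00085


class TestSimulateWell:
    def test_empty_well(self, amp1, model):
        ds = simulate_well(amp1, WellSpec({}, n_droplets=4000, seed=3), model)
        assert all(label == frozenset() for label in ds.truth)
        for amp, base, sd in zip((ds.ch1, ds.ch2), model.baseline, model.noise_sd):
            assert abs(amp.mean() - base) < 5 * sd / math.sqrt(len(ds))
            assert abs(amp.std(ddof=1) - sd) < 0.1 * sd

    def test_occupancy_at_half(self, amp1, model):
        # concentration chosen so lambda = ln 2: exactly half the droplets
        # should carry template, within binomial 99% bounds
        conc = math.log(2) / VOL
        ds = simulate_well(amp1, WellSpec({"WT": conc}, seed=11), model)
        frac = np.mean([bool(label) for label in ds.truth])
        assert abs(frac - 0.5) < 0.0091

    def test_occupancy_law_across_seeds(self, amp1, model):
        # positive fraction converges to 1 - exp(-lambda); allow one
        # 3-binomial-SD excursion in 20 seeds
        lam = 0.3
        p = 1 - math.exp(-lam)
        bound = 3 * math.sqrt(p * (1 - p) / 20000)
        excursions = 0
        for seed in range(20):
            ds = simulate_well(amp1, WellSpec({"RPP30": lam / VOL}, seed=seed), model)
            frac = np.mean(["RPP30" in label for label in ds.truth])
            excursions += abs(frac - p) > bound
        assert excursions <= 1

    def test_independent_co_loading(self, amp1, model):
        # joint positivity of two targets follows the product law; chi-square
        # independence not rejected at alpha=0.01 in >= 19 of 20 seeds
        rejections = 0
        for seed in range(20):
            ds = simulate_well(
                amp1, WellSpec({"WT": 300.0, "MT": 150.0}, seed=seed), model
            )
            wt = np.array(["WT" in label for label in ds.truth])
            mt = np.array(["MT" in label for label in ds.truth])
            table = [
                [np.sum(wt & mt), np.sum(wt & ~mt)],
                [np.sum(~wt & mt), np.sum(~wt & ~mt)],
            ]
            _, p, _, _ = stats.chi2_contingency(table)
            rejections += p < 0.01
        assert rejections <= 1

    def test_seeded_determinism(self, amp1, model):
        spec = WellSpec({"WT": 100.0, "MT": 50.0}, seed=7)
        d1 = simulate_well(amp1, spec, model)
        d2 = simulate_well(amp1, spec, model)
        assert np.array_equal(d1.ch1, d2.ch1)
        assert np.array_equal(d1.ch2, d2.ch2)
        assert d1.truth == d2.truth

    def test_negative_concentration_rejected(self, amp1, model):
        with pytest.raises(ValueError, match="negative"):
            simulate_well(amp1, WellSpec({"WT": -1.0}, seed=0), model)

    def test_unknown_target_rejected(self, amp1, model):
        with pytest.raises(KeyError, match="NOPE"):
            simulate_well(amp1, WellSpec({"NOPE": 10.0}, seed=0), model)

    def test_saturation_cap_clips(self, amp2, model):
        capped = AmplitudeModel(saturation_cap=(11000.0, 13000.0))
        ds = simulate_well(
            amp2, WellSpec({"AR-X1": 2000.0, "AR-X2": 2000.0}, seed=5), capped
        )
        # the AR-X1+AR-X2 band (baseline+13000) must be compressed below cap
        assert ds.ch1.max() < 11000.0 + 6 * capped.noise_sd[0]

    def test_rain_produces_intermediate_amplitudes(self, amp1):
        rainy = AmplitudeModel(rain_fraction=0.5)
        ds = simulate_well(amp1, WellSpec({"MT": 400.0}, seed=9), rainy)
        pos = np.array([bool(label) for label in ds.truth])
        level = amp1.target("MT").amplitude_level
        mid = (ds.ch1[pos] > 1000 + 0.2 * level) & (ds.ch1[pos] < 1000 + 0.8 * level)
        assert mid.mean() > 0.1


class TestModelValidation:
    def test_bad_noise(self):
        with pytest.raises(ValueError):
            AmplitudeModel(noise_sd=(0.0, 100.0))

    def test_bad_rain(self):
        with pytest.raises(ValueError):
            AmplitudeModel(rain_fraction=1.5)


class TestProfiles:
    def test_mix_is_mass_weighted_mean(self):
        mixed = mix_profiles(
            GENOME_PROFILES["lncap_like"], GENOME_PROFILES["vcap_like"], (2, 1)
        )
        lncap = GENOME_PROFILES["lncap_like"].copies_per_genome
        vcap = GENOME_PROFILES["vcap_like"].copies_per_genome
        for t in lncap:
            assert mixed.copies_per_genome[t] == pytest.approx(
                (2 * lncap[t] + vcap[t]) / 3
            )

    def test_mix_with_mutant_keeps_both_alleles(self, amp1, model):
        # a T877A-carrying genome diluted into a high-CN genome shows both
        # mutant and wild-type droplet populations
        mixed = mix_profiles(
            GENOME_PROFILES["lncap_like"], GENOME_PROFILES["vcap_like"], (2, 1)
        )
        ds = simulate_sample(amp1, mixed, 40.0, seed=21, model=model)
        labels = set().union(*ds.truth)
        assert "MT" in labels and "WT" in labels

    def test_sample_concentration_scaling(self, amp1, model):
        # doubling genome concentration roughly doubles occupancy at low lambda
        lo = simulate_sample(amp1, GENOME_PROFILES["male_normal"], 10.0, seed=2, model=model)
        hi = simulate_sample(amp1, GENOME_PROFILES["male_normal"], 20.0, seed=2, model=model)
        f_lo = np.mean(["RPP30" in label for label in lo.truth])
        f_hi = np.mean(["RPP30" in label for label in hi.truth])
        assert f_hi / f_lo == pytest.approx(2.0, rel=0.15)


class TestGroundTruthSidecar:
    def test_round_trip(self, amp1, model, tmp_path):
        ds = simulate_well(amp1, WellSpec({"WT": 200.0, "MT": 80.0}, n_droplets=100, seed=4), model)
        path = tmp_path / "truth.tsv"
        write_ground_truth(ds, path)
        assert read_ground_truth(path) == ds.truth
        assert sum(1 for _ in open(path)) == 101  # header + one row per droplet

    def test_empty_well_labels(self, amp1, model, tmp_path):
        ds = simulate_well(amp1, WellSpec({}, n_droplets=50, seed=4), model)
        path = tmp_path / "truth.tsv"
        write_ground_truth(ds, path)
        assert read_ground_truth(path) == [frozenset()] * 50

    def test_missing_truth_rejected(self, amp1, model, tmp_path):
        ds = simulate_well(amp1, WellSpec({}, n_droplets=10, seed=0), model)
        ds.truth = None
        with pytest.raises(ValueError, match="ground-truth"):
            write_ground_truth(ds, tmp_path / "x.tsv")
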