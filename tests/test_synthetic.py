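"""Generator correctness: determinism, calibration, planted recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import ftirquant as fq
from ftirquant.errors import ValidationError
from ftirquant.synthetic import DEFAULT_GRID


class TestSimulateSpectrum:
    def test_all_zero_model_gives_zero_trace(self):
        model = fq.SpectrumModel(band_apexes={"po2_sym": 0.0},
                                 baseline=(0.0,), noise_sd=0.0)
        s = fq.simulate_spectrum(model)
        assert np.all(s.absorbance == 0.0)

    def test_same_seed_identical_traces(self):
        model, _ = fq.preset_pair("cisplatin", seed=42)
        s1 = fq.simulate_spectrum(model)
        s2 = fq.simulate_spectrum(model)
        assert np.array_equal(s1.absorbance, s2.absorbance)

    def test_single_gaussian_apex_recovered(self):
        model = fq.SpectrumModel(band_apexes={"ch2_asym": 0.37}, eta=0.0,
                                 baseline=(0.0,), noise_sd=0.0)
        s = fq.simulate_spectrum(model)
        m = fq.measure_replicate(s)["ch2_asym"]
        assert m.intensity == pytest.approx(0.37, abs=1e-6)

    def test_baseline_polynomial_degree_capped(self):
        with pytest.raises(ValidationError):
            fq.SpectrumModel(band_apexes={}, baseline=(0.0, 1.0, 2.0, 3.0))


class TestGroupPair:
    def test_null_effect_and_zero_cv_groups_identical(self):
        model, _ = fq.preset_pair("cisplatin", seed=3)
        model = replace(model, noise_sd=0.0)
        c, t = fq.simulate_group_pair(model, fq.GroupEffect(), 2, seed=3)
        for sc, st_ in zip(c.replicates, t.replicates):
            assert np.array_equal(sc.absorbance, st_.absorbance)

    def test_noiseless_recovery_of_planted_cisplatin_metrics(
            self, noiseless_cisplatin_pair):
        c, t = noiseless_cisplatin_pair
        truth = fq.planted_truth("cisplatin")
        for metric in fq.ALL_METRICS:
            mc = fq.evaluate_metric(c, metric).mean
            mt = fq.evaluate_metric(t, metric).mean
            if metric in fq.metrics.POSITION_METRICS:
                assert abs(mc - truth["control"][metric]) < 0.25, metric
                assert abs(mt - truth["treated"][metric]) < 0.25, metric
            else:
                assert mc == pytest.approx(truth["control"][metric],
                                           rel=2e-3), metric
                assert mt == pytest.approx(truth["treated"][metric],
                                           rel=2e-3), metric

    def test_noiseless_knockdown_percent_changes(self):
        # the nearly vanished olefinic band hits an apex-picking
        # discontinuity; its recovery is ~1%, all others are exact
        model, effect = fq.preset_pair("knockdown", seed=7)
        model = replace(model, noise_sd=0.0)
        effect = replace(effect, replicate_cv=0.0, position_jitter_sd=0.0)
        c, t = fq.simulate_group_pair(model, effect, 1, seed=7)
        lp = fq.compare_groups("lipid_protein_ratio", c, t).percent_change
        assert lp == pytest.approx(fq.percent_change(1.076, 1.3018),
                                   abs=0.05)
        ole = fq.compare_groups("olefinic_index", c, t).percent_change
        assert ole == pytest.approx(fq.percent_change(0.03181, 0.00747),
                                    abs=1.0)
        rna = fq.compare_groups("rna_content_1121", c, t).percent_change
        assert rna == pytest.approx(16.68, abs=0.05)

    def test_planted_band_shifts_recovered(self):
        model, effect = fq.preset_pair("knockdown", seed=13)
        model = replace(model, noise_sd=0.0)
        effect = replace(effect, replicate_cv=0.0, position_jitter_sd=0.0)
        c, t = fq.simulate_group_pair(model, effect, 1, seed=13)
        mc = [fq.measure_replicate(s)["po2_sym"] for s in c.replicates]
        mt = [fq.measure_replicate(s)["po2_sym"] for s in t.replicates]
        shift = fq.band_shift(mc, mt)
        assert shift.shift == pytest.approx(1083.09 - 1080.92, abs=0.25)

    def test_noise_scales_estimator_spread(self):
        model, _ = fq.preset_pair("cisplatin", seed=1)
        spreads = []
        for sd in (1e-4, 1e-3):
            vals = []
            for k in range(12):
                m = replace(model, noise_sd=sd, seed=100 + k)
                s = fq.simulate_spectrum(m, f"s{k}")
                vals.append(fq.lipid_protein_ratio(fq.measure_replicate(s)))
            spreads.append(np.std(vals))
        # 10x noise should give roughly 10x spread (same band structure)
        assert 3.0 < spreads[1] / spreads[0] < 30.0

    def test_grid_is_4cm(self):
        assert np.allclose(np.diff(DEFAULT_GRID), 4.0)


class TestDegPair:
    def test_planted_counts_exact(self):
        t1, t2 = fq.simulate_deg_pair(100, 40, 60, 30, 10, 15, seed=21)
        r = fq.concordance(t1, t2, alpha=0.05)
        assert (r.n_sig_1, r.n_sig_2, r.n_shared) == (40, 60, 30)
        assert (r.n_parallel, r.n_parallel_up, r.n_parallel_down) == \
            (25, 10, 15)

    def test_no_shared_genes_r_missing(self):
        t1, t2 = fq.simulate_deg_pair(50, 10, 10, 0, 0, 0, seed=2)
        r = fq.concordance(t1, t2)
        assert r.n_shared == 0 and r.pearson_r is None

    def test_same_seed_identical_tables(self):
        a1, a2 = fq.simulate_deg_pair(80, 30, 30, 20, 5, 10, seed=17)
        b1, b2 = fq.simulate_deg_pair(80, 30, 30, 20, 5, 10, seed=17)
        pd.testing.assert_frame_equal(a1, b1)
        pd.testing.assert_frame_equal(a2, b2)

    def test_infeasible_plan_rejected(self):
        with pytest.raises(ValidationError):
            fq.simulate_deg_pair(100, 40, 60, 50, 10, 15, seed=1)

    @pytest.mark.parametrize("plan", [
        (120, 50, 70, 40, 12, 20), (60, 20, 25, 10, 0, 0),
        (300, 150, 150, 150, 75, 75),
    ])
    def test_generator_is_its_own_oracle(self, plan):
        n_genes, s1, s2, sh, up, down = plan
        t1, t2 = fq.simulate_deg_pair(*plan, seed=31)
        r = fq.concordance(t1, t2, alpha=0.05)
        assert (r.n_sig_1, r.n_sig_2, r.n_shared,
                r.n_parallel_up, r.n_parallel_down) == (s1, s2, sh, up, down)
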