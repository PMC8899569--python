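import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alleledit.fluxor import extract_traces
from alleledit.quantify import classify_sample
from alleledit.simulate import (CohortSimConfig, FluxSimConfig, ReadSimConfig,
                                expected_read_class, noise_sd_for_target_correlation,
                                population_correlation, read_fastq,
                                simulate_cohort, simulate_flux,
                                simulate_flux_stack, simulate_reads,
                                simulate_t7e1, write_fastq)


class TestReadSim:
    def test_clean_reads_are_allele_substrings(self, ref, mutant_guide, wt_seq):
        cfg = ReadSimConfig(n_reads=300, editing_rate_mutant=0.0, seed=0)
        records, truth = simulate_reads(ref, mutant_guide, cfg)
        assert not truth.edited.any()
        for (rid, seq, qual), allele in zip(records, truth.allele):
            src = ref.sequence if allele == "mutant" else wt_seq
            assert seq in src
            assert set(qual) == {"F"} and len(qual) == len(seq)

    def test_identical_seed_is_byte_identical(self, ref, mutant_guide, tmp_path):
        cfg = ReadSimConfig(n_reads=200, editing_rate_mutant=0.1,
                            substitution_error_rate=0.01, seed=42)
        a, _ = simulate_reads(ref, mutant_guide, cfg)
        b, _ = simulate_reads(ref, mutant_guide, cfg)
        assert a == b
        c, _ = simulate_reads(ref, mutant_guide,
                              ReadSimConfig(n_reads=200, editing_rate_mutant=0.1,
                                            substitution_error_rate=0.01, seed=43))
        assert c != a
        p = tmp_path / "reads.fastq.gz"
        write_fastq(a, p)
        assert [(r, s) for r, s, _ in a] == list(read_fastq(p))

    def test_edited_count_within_binomial_bound(self, ref, mutant_guide):
        # central 99.9% binomial interval computed independently of the sim
        cfg = ReadSimConfig(n_reads=100_000, editing_rate_mutant=0.006, seed=7)
        _, truth = simulate_reads(ref, mutant_guide, cfg)
        mut = truth[truth.allele == "mutant"]
        k = int((mut.edited).sum())
        lo, hi = stats.binom.interval(0.999, len(mut), 0.006)
        assert lo <= k <= hi

    def test_truth_marginals_match_allele_fraction(self, ref, mutant_guide):
        cfg = ReadSimConfig(n_reads=20_000, allele_fraction_mutant=0.3, seed=8)
        _, truth = simulate_reads(ref, mutant_guide, cfg)
        k = (truth.allele == "mutant").sum()
        lo, hi = stats.binom.interval(0.999, len(truth), 0.3)
        assert lo <= k <= hi

    def test_forced_inframe_weights(self, ref, mutant_guide):
        cfg = ReadSimConfig(n_reads=200, editing_rate_mutant=1.0,
                            indel_length_weights={-3: 1.0}, seed=9)
        _, truth = simulate_reads(ref, mutant_guide, cfg)
        edited = truth[truth.edited]
        assert (edited.indel_len == -3).all()

    def test_error_free_reads_roundtrip_through_classifier(self, ref,
                                                           mutant_guide):
        cfg = ReadSimConfig(n_reads=500, editing_rate_mutant=0.2, seed=10)
        records, truth = simulate_reads(ref, mutant_guide, cfg)
        truth = truth.set_index("read_id")
        for rid, cls, _ in classify_sample(
                ((r, s) for r, s, _ in records), ref, mutant_guide):
            row = truth.loc[rid]
            assert cls == expected_read_class(row.allele, row.edited,
                                              row.indel_len)

    def test_editing_without_weights_is_config_error(self):
        with pytest.raises(ValueError, match="weights"):
            ReadSimConfig(n_reads=10, editing_rate_mutant=0.5,
                          indel_length_weights={-3: 0.0})

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            ReadSimConfig(n_reads=10, editing_rate_mutant=1.5)
        with pytest.raises(ValueError):
            ReadSimConfig(n_reads=0)


class TestCohortSim:
    def test_noiseless_shift_is_exactly_linear(self):
        # effect kept small enough that no threshold hits the instrument floor
        cfg = CohortSimConfig(n_mice=10, noise_sd_db=0.0, db_per_percent=10.0,
                              efficacy_mean=2.0, efficacy_sd=0.5, seed=0)
        table, truth = simulate_cohort(cfg)
        for _, row in table.merge(truth, on="mouse_id").iterrows():
            shifts = [row[f"con_{f}kHz"] - row[f"inj_{f}kHz"]
                      for f in (6, 12, 18, 24, 30)]
            assert np.mean(shifts) == pytest.approx(
                10.0 * row.true_efficacy, abs=1e-9)

    def test_degenerate_efficacy_flagged(self):
        cfg = CohortSimConfig(n_mice=5, efficacy_sd=0.0, seed=1)
        table, _ = simulate_cohort(cfg)
        assert table.degenerate_efficacy.all()
        assert table.efficacy_percent.nunique() == 1

    def test_efficacy_nonnegative_and_thresholds_in_range(self):
        cfg = CohortSimConfig(n_mice=200, efficacy_mean=1.0, efficacy_sd=3.0,
                              noise_sd_db=20.0, seed=2)
        table, _ = simulate_cohort(cfg)
        assert (table.efficacy_percent >= 0).all()
        thr = table.filter(regex="kHz$")
        assert (thr >= 10).all().all() and (thr <= 95).all().all()

    def test_closed_form_correlation_inversion(self):
        tau = noise_sd_for_target_correlation(0.5, db_per_percent=1.0,
                                              efficacy_sd=3.0)
        assert population_correlation(1.0, 3.0, tau) == pytest.approx(0.5)

    def test_reproducible_by_seed(self):
        cfg = CohortSimConfig(n_mice=8, seed=11)
        a, _ = simulate_cohort(cfg)
        b, _ = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)


class TestT7E1Sim:
    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (100.0, 1.0),
                                            (50.0, 0.75)])
    def test_noiseless_fraction(self, p, expected):
        cleaved, uncut = simulate_t7e1(p, density_noise_sd=0.0)
        assert cleaved == pytest.approx(expected)
        assert cleaved + uncut == pytest.approx(1.0)

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            simulate_t7e1(120.0)

    def test_noisy_densities_nonnegative(self):
        rng = np.random.default_rng(0)
        for p in (0, 5, 50, 95):
            c, u = simulate_t7e1(p, density_noise_sd=0.3, seed=rng)
            assert c >= 0 and u >= 0


class TestFluxSim:
    def test_zero_slope_zero_noise_is_constant(self):
        cfg = FluxSimConfig(n_rois=2, slope_by_group={"ctrl": 0.0},
                            noise_sd=0.0, f0_sd=0.0, seed=0)
        traces, truth = simulate_flux(cfg)
        for tr in traces:
            assert np.allclose(tr.f, tr.f[0])
        assert (truth.true_slope == 0).all()

    def test_stack_pixel_means_reproduce_traces(self):
        cfg = FluxSimConfig(n_rois=5, noise_sd=0.0, seed=3)
        stack, masks, groups, truth = simulate_flux_stack(cfg)
        traces = extract_traces(stack, masks, frame_interval_s=cfg.frame_interval_s,
                                groups=groups)
        expected, _ = simulate_flux(cfg)
        for got, want in zip(traces, expected):
            assert got.roi_id == want.roi_id
            np.testing.assert_allclose(got.f, want.f, rtol=0, atol=1e-12)

    def test_roi_masks_are_disjoint(self):
        from alleledit.simulate import make_roi_grid
        masks, _ = make_roi_grid(7)
        total = sum(m.sum() for m in masks.values())
        union = np.zeros_like(next(iter(masks.values())), dtype=int)
        for m in masks.values():
            union += m
        assert union.max() == 1 and total == union.sum()
        with pytest.raises(ValueError, match="overlap"):
            make_roi_grid(4, gap=0)
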