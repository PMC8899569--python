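import numpy as np
import pytest

from alleledit.align import align_read
from alleledit.quantify import (QuantConfig, background_correct, call_indels,
                                call_marker, classify_read, quantify_sample)
from alleledit.simulate import ReadSimConfig, simulate_reads

from oracles import classify_oracle

CUT = 53  # cut offset of the knock-in guide position on the fixture


def _aligned(ref, read):
    return align_read(read, ref)


class TestCallMarker:
    def test_mutant_base_a(self, ref):
        ar = _aligned(ref, ref.sequence)
        assert call_marker(ar, ref) == "mutant"

    def test_wt_base_c(self, ref, wt_seq):
        ar = _aligned(ref, wt_seq)
        assert call_marker(ar, ref) == "wt"

    def test_third_base_is_other(self, ref):
        read = ref.sequence[:40] + "G" + ref.sequence[41:]
        assert call_marker(_aligned(ref, read), ref) == "other"

    def test_deletion_spanning_marker_is_other(self, ref):
        read = ref.sequence[:38] + ref.sequence[44:]
        ar = _aligned(ref, read)
        assert call_marker(ar, ref) == "other"

    def test_uncovered_marker_is_none(self, ref):
        ar = _aligned(ref, ref.sequence[45:])
        assert call_marker(ar, ref) is None


class TestCallIndels:
    def test_perfect_read_has_no_window_indels(self, ref):
        ar = _aligned(ref, ref.sequence)
        assert call_indels(ar, CUT) == []

    def test_insertion_at_cut(self, ref):
        read = ref.sequence[:53] + "T" + ref.sequence[53:]
        ar = _aligned(ref, read)
        calls = call_indels(ar, CUT)
        assert len(calls) == 1
        assert calls[0][1] == +1

    def test_distant_deletion_outside_window(self, ref):
        # deletion 12 nt from the cut with halfwidth 5: outside [48, 58]
        read = ref.sequence[:70] + ref.sequence[72:]
        ar = _aligned(ref, read)
        dels = [op for op in ar.ops if op.op == "D"]
        assert dels and dels[0].ref_offset - CUT >= 12
        assert call_indels(ar, CUT, QuantConfig(window_halfwidth=5)) == []
        assert call_indels(ar, CUT, QuantConfig(window_halfwidth=20)) != []


class TestClassifyRule:
    @pytest.mark.parametrize("marker", ["mutant", "wt", "other", None])
    @pytest.mark.parametrize("L", range(-9, 10))
    def test_rule_table_matches_oracle(self, marker, L):
        indels = [(CUT, L, "")] if L != 0 else []
        got = classify_read(marker, indels)
        assert got == classify_oracle(marker, L, has_indel=bool(indels))

    def test_failed_alignment_is_discarded(self):
        assert classify_read("mutant", [], aligned_ok=False) == "discarded"

    def test_net_zero_multi_indel_is_excluded(self):
        assert classify_read("mutant", [(CUT, +2, "AG"), (CUT + 3, -2, "")]) \
            == "mutant_excluded"

    def test_multi_indels_summed_before_frame_test(self):
        # +2 and -1 net to +1: out of frame, edited
        assert classify_read("mutant", [(CUT, +2, "AG"), (CUT + 3, -1, "")]) \
            == "mutant_edited"


class TestQuantifySample:
    def test_zero_editing_gives_zero_efficacy(self, ref, mutant_guide):
        cfg = ReadSimConfig(n_reads=400, editing_rate_mutant=0.0, seed=1)
        records, _ = simulate_reads(ref, mutant_guide, cfg)
        res = quantify_sample(((r, s) for r, s, _ in records), ref,
                              mutant_guide)
        assert res.efficacy_defined
        assert res.efficacy_percent == 0.0
        assert res.counts["mutant_edited"] == 0
        assert sum(res.counts.values()) == res.total_reads == 400

    def test_inframe_only_editing_counts_as_excluded(self, ref, mutant_guide):
        cfg = ReadSimConfig(n_reads=400, editing_rate_mutant=0.5,
                            indel_length_weights={-3: 1.0}, seed=2)
        records, truth = simulate_reads(ref, mutant_guide, cfg)
        res = quantify_sample(((r, s) for r, s, _ in records), ref,
                              mutant_guide)
        assert res.efficacy_percent == 0.0
        assert res.counts["mutant_excluded"] > 0
        assert res.counts["mutant_excluded"] == int(
            ((truth.allele == "mutant") & truth.edited).sum())

    def test_efficacy_recovery_small(self, ref, mutant_guide):
        cfg = ReadSimConfig(n_reads=4000, editing_rate_mutant=0.3,
                            substitution_error_rate=0.001, seed=3)
        records, truth = simulate_reads(ref, mutant_guide, cfg)
        res = quantify_sample(((r, s) for r, s, _ in records), ref,
                              mutant_guide)
        mut = truth[truth.allele == "mutant"]
        out_of_frame = mut.edited & mut.indel_len.map(
            lambda L: L != 0 and abs(L) <= 8 and L % 3 != 0)
        true_eff = 100.0 * out_of_frame.mean()
        n = len(mut)
        se = 100.0 * np.sqrt(true_eff / 100 * (1 - true_eff / 100) / n)
        assert abs(res.efficacy_percent - true_eff) < 3 * se

    def test_zero_marker_positive_flags_undefined(self, ref, mutant_guide):
        cfg = ReadSimConfig(n_reads=50, allele_fraction_mutant=0.0, seed=4)
        records, _ = simulate_reads(ref, mutant_guide, cfg)
        res = quantify_sample(((r, s) for r, s, _ in records), ref,
                              mutant_guide)
        assert not res.efficacy_defined
        assert res.efficacy_percent is None

    def test_empty_read_set_is_an_error(self, ref, mutant_guide):
        with pytest.raises(ValueError, match="empty"):
            quantify_sample(iter(()), ref, mutant_guide)

    def test_substitution_errors_never_create_edits(self, ref, mutant_guide):
        # raising the substitution rate cannot raise mutant_edited when true
        # editing is zero: edits require indels, not substitutions
        edited_counts = []
        for err in (0.0, 0.01, 0.05):
            cfg = ReadSimConfig(n_reads=500, editing_rate_mutant=0.0,
                                substitution_error_rate=err, seed=5)
            records, _ = simulate_reads(ref, mutant_guide, cfg)
            res = quantify_sample(((r, s) for r, s, _ in records), ref,
                                  mutant_guide)
            edited_counts.append(res.counts["mutant_edited"])
        assert edited_counts == [0, 0, 0]


class TestBackgroundCorrect:
    def _result(self, ref, guide, editing, seed):
        cfg = ReadSimConfig(n_reads=300, editing_rate_mutant=editing,
                            seed=seed)
        records, _ = simulate_reads(ref, guide, cfg)
        return quantify_sample(((r, s) for r, s, _ in records), ref, guide)

    def test_zero_control_passes_through(self, ref, mutant_guide):
        inj = self._result(ref, mutant_guide, 0.3, 6)
        ctl = self._result(ref, mutant_guide, 0.0, 7)
        corr = background_correct(inj, ctl)
        assert corr.control_percent == 0.0
        assert corr.corrected_percent == inj.efficacy_percent
        assert not corr.floored

    def test_subtraction_arithmetic(self, ref, mutant_guide):
        inj = self._result(ref, mutant_guide, 0.3, 8)
        ctl = self._result(ref, mutant_guide, 0.1, 9)
        corr = background_correct(inj, ctl)
        assert corr.corrected_percent == pytest.approx(
            inj.efficacy_percent - ctl.efficacy_percent)

    def test_control_above_injected_floors_to_zero(self, ref, mutant_guide):
        inj = self._result(ref, mutant_guide, 0.0, 10)
        ctl = self._result(ref, mutant_guide, 0.2, 11)
        corr = background_correct(inj, ctl)
        assert corr.corrected_percent == 0.0
        assert corr.floored

    def test_config_mismatch_is_an_error(self, ref, mutant_guide):
        from alleledit.quantify import quantify_sample as q
        cfg = ReadSimConfig(n_reads=100, seed=12)
        records, _ = simulate_reads(ref, mutant_guide, cfg)
        a = q(((r, s) for r, s, _ in records), ref, mutant_guide,
              QuantConfig(window_halfwidth=5))
        b = q(((r, s) for r, s, _ in records), ref, mutant_guide,
              QuantConfig(window_halfwidth=6))
        with pytest.raises(ValueError, match="different"):
            background_correct(a, b)
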