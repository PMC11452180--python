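"""Cluster placement by level-set descent, code-map assembly, comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pccd.clusters import (
    assemble_code_map,
    compare_code_maps,
    detect_clusters,
    mean_positive_count,
    place_cluster,
)
from pccd.datamodel import Peak, PeakConfig, ValidationError
from pccd.ordering import cohort_sequences
from pccd.synthetic import TFSpec, generate_cohort

from conftest import make_sequences, zero_noise_config


def triangle(apex_rank=20, L=40, slope=0.1, height=1.0):
    """Symmetric triangular profile peaking at ``apex_rank``."""
    i = np.arange(1, L + 1)
    return np.clip(height - slope * np.abs(i - apex_rank), 0.0, None)


class TestMeanPositiveCount:
    def test_hand_count(self):
        """3 and 4 positives inside [4,9] across two sequences -> n = 3.5."""
        s1 = [0, 0, 0, 1, 1, 0, 1, 0, 0, 0]
        s2 = [1, 0, 0, 1, 1, 1, 0, 1, 0, 0]
        assert mean_positive_count(make_sequences([s1, s2]), (4, 9)) == 3.5

    def test_all_negative(self):
        assert mean_positive_count(make_sequences([[0] * 6] * 3), (1, 6)) == 0.0

    def test_planted_block_no_noise(self):
        calls = [0] * 5 + [1] * 5 + [0] * 5
        assert mean_positive_count(make_sequences([calls] * 4), (1, 15)) == 5.0

    def test_short_sequences_contribute_observed_ranks_only(self):
        seqs = make_sequences([[1, 1, 1, 1], [1, 1]])  # second stops at rank 2
        assert mean_positive_count(seqs, (1, 4)) == 3.0  # (4 + 2) / 2

    def test_invalid_region(self):
        with pytest.raises(ValidationError):
            mean_positive_count(make_sequences([[1]]), (3, 2))


class TestPlaceCluster:
    def test_integer_n_on_symmetric_triangle(self):
        """n=5 on a triangle at rank 20 covers exactly [18,22]."""
        x = triangle()
        pk = Peak(position=20, height=1.0, prominence=1.0, region=(1, 40))
        call = place_cluster(x, pk, 5.0)
        assert call.core_span == (18, 22)
        assert call.coverage == {r: 1.0 for r in range(18, 23)}

    def test_fractional_n_splits_borders(self):
        """n=4.6 covers [19,21] fully, borders 18 and 22 at 0.8 each."""
        x = triangle()
        pk = Peak(position=20, height=1.0, prominence=1.0, region=(1, 40))
        call = place_cluster(x, pk, 4.6)
        assert call.core_span == (19, 21)
        assert call.coverage[18] == pytest.approx(0.8, abs=1e-6)
        assert call.coverage[22] == pytest.approx(0.8, abs=1e-6)
        assert sum(call.coverage.values()) == pytest.approx(4.6, abs=1e-9)

    def test_zero_n_empty_call(self):
        pk = Peak(position=20, height=1.0, prominence=1.0, region=(1, 40))
        call = place_cluster(triangle(), pk, 0.0)
        assert call.coverage == {} and call.core_span is None and call.span is None

    def test_sub_cell_n_sits_on_peak_rank(self):
        pk = Peak(position=20, height=1.0, prominence=1.0, region=(1, 40))
        call = place_cluster(triangle(), pk, 0.4)
        assert call.coverage == {20: 0.4}

    def test_asymmetric_peak_splits_remainder_by_overhang(self):
        """On a peak falling twice as fast on the right, the left border gets
        the larger share of the fractional remainder."""
        i = np.arange(1, 41, dtype=float)
        x = np.clip(1.0 - np.where(i <= 20, 0.05 * (20 - i), 0.1 * (i - 20)), 0, None)
        pk = Peak(position=20, height=1.0, prominence=1.0, region=(1, 40))
        call = place_cluster(x, pk, 7.5)
        assert sum(call.coverage.values()) == pytest.approx(7.5, abs=1e-9)
        lo, hi = call.span
        assert call.coverage[lo] > call.coverage[hi]
        # interpolated cut: level L has width (L drop)/0.05 + (L drop)/0.1 + 1
        # = 7.5 -> drop = 0.2166..; edges at 20 - 4.33 and 20 + 2.166
        assert call.core_span == (16, 22)
        assert call.coverage[15] == pytest.approx(1 / 3, abs=1e-3)
        assert call.coverage[23] == pytest.approx(1 / 6, abs=1e-3)

    def test_saturation_caps_coverage(self, caplog):
        x = triangle()
        pk = Peak(position=20, height=1.0, prominence=1.0, region=(18, 22))
        with caplog.at_level("WARNING"):
            call = place_cluster(x, pk, 9.0)
        assert call.saturated
        assert call.coverage == {r: 1.0 for r in range(18, 23)}
        assert "exceeds region capacity" in caplog.text

    def test_cluster_confined_to_region(self):
        """The level-set component is clipped to the peak's prevailing region."""
        x = triangle()
        pk = Peak(position=20, height=1.0, prominence=1.0, region=(20, 40))
        call = place_cluster(x, pk, 4.0)
        assert min(call.coverage) >= 20
        assert sum(call.coverage.values()) == pytest.approx(4.0, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=80)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(min_value=0.0, max_value=30.0),
    )
    def test_coverage_conservation_random(self, seed, n):
        """Sum of coverages equals n (or saturates at capacity) on arbitrary
        smoothed-looking profiles; no rank ever exceeds coverage 1."""
        rng = np.random.default_rng(seed)
        L = int(rng.integers(3, 50))
        x = rng.uniform(0, 1, size=L)
        p0 = int(np.argmax(x))
        pk = Peak(position=p0 + 1, height=float(x[p0]), prominence=1.0, region=(1, L))
        call = place_cluster(x, pk, min(n, L + 5))
        total = sum(call.coverage.values())
        assert all(0 <= v <= 1 + 1e-12 for v in call.coverage.values())
        if call.saturated:
            assert total == pytest.approx(L, abs=1e-9)
        else:
            assert total == pytest.approx(min(n, L + 5), abs=1e-9)
        if call.coverage:
            lo, hi = call.span
            assert set(call.coverage) == set(range(lo, hi + 1))  # contiguous


class TestDetectClusters:
    def test_single_planted_block_recovered_exactly(self, zero_noise_cohort):
        sset, truths = zero_noise_cohort
        seqs = cohort_sequences(sset, "one")
        (call,) = detect_clusters(seqs, "one")
        assert call.called_span == (16, 23)
        assert call.n == 8.0

    def test_two_planted_blocks_recovered(self, zero_noise_cohort):
        sset, _ = zero_noise_cohort
        seqs = cohort_sequences(sset, "two")
        calls = detect_clusters(seqs, "two")
        assert [c.called_span for c in calls] == [(5, 11), (27, 33)]
        assert [c.n for c in calls] == [7.0, 7.0]

    def test_all_negative_cohort_yields_no_clusters(self):
        seqs = make_sequences([[0] * 30] * 20)
        assert detect_clusters(seqs, "TF1") == []


def make_call(tf, lo, hi, cov_border=None):
    from pccd.datamodel import ClusterCall

    cov = {r: 1.0 for r in range(lo, hi + 1)}
    if cov_border:
        cov.update(cov_border)
    pk = Peak(position=(lo + hi) // 2, height=0.9, prominence=0.9, region=(1, 40))
    return ClusterCall(
        tf=tf, peak=pk, n=sum(cov.values()), core_span=(lo, hi), coverage=cov
    )


class TestAssembleCodeMap:
    _call = staticmethod(make_call)

    def test_direct_assembly(self):
        cm = assemble_code_map(
            [self._call("Jim", 16, 23), self._call("Nvy", 25, 32)], condition="control"
        )
        assert cm.code_at(20) == {"Jim"}
        assert cm.code_at(26) == {"Nvy"}
        assert cm.code_at(24) == set()

    def test_empty_calls_all_zero(self):
        cm = assemble_code_map([])
        assert cm.tfs == []
        assert cm.code_at(5) == set()

    def test_border_coverage_propagates(self):
        call = self._call("Jim", 16, 23, cov_border={24: 0.8})
        cm = assemble_code_map([call])
        assert cm.membership("Jim", 24) == pytest.approx(0.8)
        assert cm.membership("Jim", 20) == 1.0

    def test_supernumerary_ranks_kept_in_annex(self):
        call = self._call("Nvy", 27, 33)
        cm = assemble_code_map([call], max_birth_order=29)
        assert cm.entries["Nvy"].keys() == set(range(27, 30))
        assert cm.annex["Nvy"].keys() == set(range(30, 34))
        assert cm.membership("Nvy", 32) == 1.0

    def test_conflicting_duplicate_calls_rejected(self):
        with pytest.raises(ValidationError, match="conflicting duplicate"):
            assemble_code_map([self._call("Jim", 16, 23), self._call("Jim", 20, 26)])


class TestCompareCodeMaps:
    def test_identical_maps_zero_deltas(self):
        a = assemble_code_map([make_call("Jim", 16, 23)])
        b = assemble_code_map([make_call("Jim", 16, 23)])
        rep = compare_code_maps(a, b)
        jim = rep["tfs"]["Jim"]
        assert jim["delta_total"] == 0.0
        assert jim["per_rank_delta"] == {}
        assert not jim["lost_clusters"] and not jim["gained_clusters"] and not jim["extended"]

    def test_extension_toward_nb_is_flagged(self):
        """Extending Jim by 7 ranks toward the NB-proximal end reports +7
        expected positives and an NB-proximal extension."""
        mk = make_call
        a = assemble_code_map([mk("Jim", 16, 23)], condition="control")
        b = assemble_code_map([mk("Jim", 16, 30)], condition="imp_oe")
        jim = compare_code_maps(a, b)["tfs"]["Jim"]
        assert jim["delta_total"] == pytest.approx(7.0)
        (ext,) = jim["extended"]
        assert ext["direction"] == "NB-proximal" and ext["added_ranks"] == 7

    def test_lost_cluster_is_flagged(self):
        mk = make_call
        a = assemble_code_map([mk("RunxA", 5, 12), mk("RunxA", 28, 36)])
        b = assemble_code_map([mk("RunxA", 5, 12)])
        runxa = compare_code_maps(a, b)["tfs"]["RunxA"]
        assert runxa["lost_clusters"] == [[28, 36]]
        assert runxa["gained_clusters"] == []

    def test_panel_mismatch_rejected(self):
        mk = make_call
        a = assemble_code_map([mk("Jim", 16, 23)])
        b = assemble_code_map([mk("Nvy", 16, 23)])
        with pytest.raises(ValidationError, match="panels differ"):
            compare_code_maps(a, b)
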