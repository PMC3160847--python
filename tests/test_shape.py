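"""Peakedness, dominant peak, peak calling and tissue specificity."""

import math

import numpy as np
import pytest

import promshape as ps
from conftest import random_tssd


def tssd(counts, **kw):
    defaults = dict(id="t", chrom="chr1", strand="+", anchor=0)
    defaults.update(kw)
    return ps.TSSD(counts=np.asarray(counts), **defaults)


class TestWidthAndMode:
    def test_single_position_width_one(self):
        assert ps.tssd_width(tssd([200])) == 1

    def test_width_is_trimmed_span(self):
        assert ps.tssd_width(tssd([3, 0, 1])) == 3

    def test_width_invariant_under_rescaling(self, rng):
        t = random_tssd(rng)
        assert ps.tssd_width(t) == ps.tssd_width(tssd(t.counts * 9))

    @pytest.mark.parametrize("counts,expected", [([1, 5, 2], 1), ([3, 3], 0), ([7], 0)])
    def test_dominant_peak_five_prime_tiebreak(self, counts, expected):
        assert ps.dominant_peak(tssd(counts)) == expected


class TestPeakedness:
    def test_delta_attains_one(self):
        assert ps.peakedness(tssd([150])) == 1.0

    def test_uniform_ten_positions(self):
        assert ps.peakedness(tssd([10] * 10)) == pytest.approx(0.01)

    def test_concentrating_mass_never_decreases(self, rng):
        t = random_tssd(rng, width=8, n_tags=60)
        counts = t.counts.copy()
        mode = int(np.argmax(counts))
        donor = next(i for i in range(8) if i != mode and counts[i] > 0 and i not in (0, 7))
        before = ps.peakedness(t)
        counts[donor] -= 1
        counts[mode] += 1
        if counts[0] > 0 and counts[-1] > 0:
            assert ps.peakedness(tssd(counts)) >= before

    def test_intra_cluster_mean(self):
        members = [tssd([10]), tssd([5, 5])]  # P = 1.0 and 0.25
        assert ps.intra_cluster_peakedness(members) == pytest.approx(0.625)
        assert ps.intra_cluster_peakedness([members[0]]) == 1.0

    def test_intra_cluster_mean_within_bounds(self, rng):
        members = [random_tssd(rng, id_=str(i)) for i in range(6)]
        scores = [ps.peakedness(t) for t in members]
        m = ps.intra_cluster_peakedness(members)
        assert min(scores) <= m <= max(scores)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            ps.intra_cluster_peakedness([])


class TestIntraClusterDissimilarity:
    def test_values(self, rng):
        ids = ("a", "b", "c")
        d = np.array([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]])
        mat = ps.DissimilarityMatrix(ids, d)
        assert ps.intra_cluster_dissimilarity(["a", "b"], mat) == pytest.approx(0.2)
        assert ps.intra_cluster_dissimilarity(list(ids), mat) == pytest.approx(0.4)
        assert ps.intra_cluster_dissimilarity(["a"], mat) == 0.0

    def test_unknown_member_rejected(self):
        mat = ps.DissimilarityMatrix(("a",), np.zeros((1, 1)))
        with pytest.raises(KeyError):
            ps.intra_cluster_dissimilarity(["a", "zz"], mat)


class TestCallPeaks:
    def test_delta_gives_one_peak(self):
        pc = ps.call_peaks(tssd([100]))
        assert pc.peaks == [0] and not pc.uniform

    def test_separated_candidates_both_called(self):
        counts = np.zeros(31, dtype=int)
        counts[0] = counts[30] = 50
        pc = ps.call_peaks(tssd(counts))
        assert pc.peaks == [0, 30]

    def test_close_candidates_merge_keeping_five_prime(self):
        counts = np.zeros(9, dtype=int)
        counts[0] = counts[8] = 50
        pc = ps.call_peaks(tssd(counts))
        assert pc.peaks == [0]  # 8 nt <= span/2: one peak, 5' tie-break

    def test_below_threshold_everywhere_is_uniform(self):
        pc = ps.call_peaks(tssd([4] * 25))  # every position 4% < 5%
        assert pc.uniform and pc.peaks == [] and pc.n_peaks == 0

    def test_threshold_is_inclusive(self):
        pc = ps.call_peaks(tssd([1] * 20), intensity=0.05)  # exactly 5% each
        assert not pc.uniform

    def test_accepted_peaks_separated_by_more_than_half_span(self, rng):
        for _ in range(30):
            t = random_tssd(rng, width=60, n_tags=200)
            pc = ps.call_peaks(t)
            gaps = np.diff(pc.peaks)
            assert np.all(gaps > pc.span / 2)

    def test_accepted_peaks_dominate_their_window(self, rng):
        # each accepted peak carries at least the mass of any unsuppressed
        # candidate within span/2
        for _ in range(30):
            t = random_tssd(rng, width=40, n_tags=300)
            probs = t.counts / t.n
            pc = ps.call_peaks(t)
            for i, p in enumerate(pc.peaks):
                others = [q for q in pc.peaks if q != p]
                window = [
                    j
                    for j in np.flatnonzero(probs >= pc.intensity)
                    if abs(j - p) <= pc.span / 2
                    and all(abs(j - q) > pc.span / 2 for q in others)
                ]
                assert all(probs[p] >= probs[j] or j == p for j in window)


class TestKlSpecificity:
    def test_identical_distributions_give_zero(self):
        q = {f"t{i}": 1 / 4 for i in range(4)}
        td = ps.TissueDistribution(p=dict(q), q=q)
        assert ps.kl_tissue_specificity(td) == pytest.approx(0.0)

    def test_single_tissue_vs_uniform_22(self):
        q = {f"t{i}": 1 / 22 for i in range(22)}
        p = {"t0": 1.0}
        td = ps.TissueDistribution(p=p, q=q)
        assert ps.kl_tissue_specificity(td) == pytest.approx(math.log2(22), abs=1e-9)
        assert ps.kl_tissue_specificity(td) == pytest.approx(4.4594, abs=1e-4)

    def test_non_negative_on_random_pairs(self, rng):
        for _ in range(100):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            td = ps.TissueDistribution(
                p={str(i): v for i, v in enumerate(p)},
                q={str(i): v for i, v in enumerate(q)},
            )
            assert ps.kl_tissue_specificity(td) >= 0

    def test_mass_outside_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            ps.TissueDistribution(p={"a": 1.0}, q={"b": 1.0})

    def test_tissue_distribution_from_tssds(self):
        t1 = tssd([6, 4], tissue_counts={"liver": 10})
        t2 = tssd([10], id="u", tissue_counts={"brain": 10})
        td = ps.tissue_distribution(t1, [t1, t2])
        assert td.p == {"liver": 1.0}
        assert td.q == {"liver": 0.5, "brain": 0.5}
        assert ps.kl_tissue_specificity(td) == pytest.approx(1.0)  # log2(2)


class TestClassSeparation:
    def test_peakedness_medians_ordered_across_classes(self, sim300):
        tssds, truth = sim300
        tc = truth.classes()
        med = {}
        for cls in ("ultra-dense", "dense", "scattered"):
            med[cls] = np.median(
                [ps.peakedness(t) for t in tssds if tc[t.id] == cls]
            )
        assert med["ultra-dense"] > med["dense"] > med["scattered"]

    def test_planted_peak_counts_recovered(self):
        tssds, truth = ps.simulate_tssds((200, 0, 0), seed=11)
        by_id = truth.by_id()
        hits = sum(
            ps.call_peaks(t).n_peaks == by_id[t.id].n_peaks for t in tssds
        )
        assert hits >= 0.95 * len(tssds)

    def test_called_peaks_near_planted_centres(self):
        tssds, truth = ps.simulate_tssds((50, 0, 0), seed=5)
        by_id = truth.by_id()
        for t in tssds:
            pc = ps.call_peaks(t)
            planted = by_id[t.id].peak_offsets
            if pc.n_peaks == len(planted):
                for got, want in zip(pc.peaks, planted):
                    assert abs(got - want) <= 3
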