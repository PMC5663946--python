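import math

import numpy as np
import pytest
from scipy import stats

from chromnet.intervals import GenomicInterval, InteractionCall
from chromnet.loops import (
    ContactMatrix,
    PeakPairCount,
    benjamini_hochberg,
    call_hic,
    call_hichip,
    hypergeometric_pvalue,
    local_filter_expected,
    read_contact_matrix,
    write_contact_matrix,
)


class TestHypergeometric:
    def test_hand_enumeration(self):
        # C(2,2)*C(8,0)/C(10,2) = 1/45
        p = hypergeometric_pvalue(PeakPairCount(0, 1, 2, 2, 2, 10))
        assert p == pytest.approx(1 / 45)

    def test_zero_draws_upper_tail_is_one(self):
        assert hypergeometric_pvalue(PeakPairCount(0, 1, 0, 5, 5, 20)) == 1.0

    def test_forced_outcome(self):
        assert hypergeometric_pvalue(PeakPairCount(0, 1, 2, 4, 2, 4)) == pytest.approx(1.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            PeakPairCount(0, 1, 3, 2, 5, 10)

    def test_matches_exhaustive_enumeration(self):
        # sum the hypergeometric pmf tail directly for all k, N <= 12
        for N in (6, 9, 12):
            for n_i in (2, 4):
                for n_j in (2, 3):
                    for k in range(0, min(n_i, n_j) + 1):
                        expected = sum(
                            math.comb(n_i, x) * math.comb(N - n_i, n_j - x) / math.comb(N, n_j)
                            for x in range(k, min(n_i, n_j) + 1)
                        )
                        got = hypergeometric_pvalue(PeakPairCount(0, 1, k, n_i, n_j, N))
                        assert got == pytest.approx(expected, abs=1e-12)


class TestBenjaminiHochberg:
    def test_all_rejected_at_boundary(self):
        q, rej = benjamini_hochberg([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert rej.all()

    def test_single_p_of_one(self):
        q, rej = benjamini_hochberg([1.0], q=0.2)
        assert not rej.any() and q[0] == 1.0

    def test_sorted_qvalues_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        q, _ = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_empty(self):
        q, rej = benjamini_hochberg([])
        assert q.size == 0 and rej.size == 0


def _uniform_pairs(rng, peaks, n, weight_pair=None, extra=0):
    pairs = []
    for _ in range(n):
        i, j = sorted(rng.choice(len(peaks), 2, replace=False).tolist())
        pairs.append((i, j))
    if weight_pair is not None:
        pairs.extend([weight_pair] * extra)
    calls = []
    for i, j in pairs:
        calls.append(
            InteractionCall(
                GenomicInterval("chr1", peaks[i].start + 5, peaks[i].start + 90),
                GenomicInterval("chr1", peaks[j].start + 5, peaks[j].start + 90),
            )
        )
    return calls


class TestCallHichip:
    @pytest.fixture
    def peaks(self):
        return [GenomicInterval("chr1", i * 10_000, i * 10_000 + 500) for i in range(40)]

    def test_planted_pair_called(self, peaks):
        rng = np.random.default_rng(1)
        pairs = _uniform_pairs(rng, peaks, 1500, weight_pair=(3, 17), extra=50)
        calls = call_hichip(pairs, peaks, extension=0)
        hits = {(c.anchor1.start // 10_000, c.anchor2.start // 10_000) for c in calls}
        assert (3, 17) in hits

    def test_min_pet_filter_excludes_significant_small_pairs(self, peaks):
        # a significant pair below the PET floor is dropped regardless of q
        rng = np.random.default_rng(2)
        pairs = _uniform_pairs(rng, peaks, 300, weight_pair=(5, 9), extra=15)
        k59 = sum(
            1
            for c in pairs
            if (c.anchor1.start // 10_000, c.anchor2.start // 10_000) == (5, 9)
        )
        with_pair = call_hichip(pairs, peaks, extension=0, min_pet=k59)
        assert any(c.pet_count == k59 for c in with_pair)
        without = call_hichip(pairs, peaks, extension=0, min_pet=k59 + 1)
        assert all(c.pet_count != k59 for c in without)

    def test_off_peak_pairs_dropped(self, peaks):
        off = InteractionCall(
            GenomicInterval("chr1", 900_000_000, 900_000_100),
            GenomicInterval("chr1", 900_500_000, 900_500_100),
        )
        assert call_hichip([off], peaks, extension=0) == []

    def test_order_invariance(self, peaks):
        rng = np.random.default_rng(3)
        pairs = _uniform_pairs(rng, peaks, 800, weight_pair=(2, 30), extra=40)
        rev = list(reversed(pairs))
        key = lambda cs: [(c.anchor1.start, c.anchor2.start, c.pet_count) for c in cs]
        assert key(call_hichip(pairs, peaks, extension=0)) == key(
            call_hichip(rev, peaks, extension=0)
        )

    def test_empty_peaks_error(self):
        with pytest.raises(ValueError):
            call_hichip([], [], extension=0)


class TestLocalFilters:
    def test_constant_field_mean(self):
        m = ContactMatrix("chr1", 1000, np.full((40, 40), 6))
        exp = local_filter_expected(m, 15, 25, P=2, W=4)
        assert all(v == pytest.approx(6.0) for v in exp.values())

    def test_all_zero_except_tested_cell(self):
        c = np.zeros((40, 40), dtype=int)
        c[15, 25] = 99
        m = ContactMatrix("chr1", 1000, c)
        exp = local_filter_expected(m, 15, 25, P=2, W=4)
        assert all(v == 0.0 for v in exp.values())

    def test_poisson_field_recovers_rate(self):
        lam = 9.0
        rng = np.random.default_rng(4)
        m = ContactMatrix("chr1", 1000, np.triu(rng.poisson(lam, size=(60, 60))))
        exp = local_filter_expected(m, 20, 40, P=2, W=4)
        for name, v in exp.items():
            # 3 standard errors for a mean of Poisson counts over >= 8 cells
            assert abs(v - lam) < 3 * math.sqrt(lam / 8), name

    def test_parameter_validation(self):
        m = ContactMatrix("chr1", 1000, np.zeros((10, 10), dtype=int))
        with pytest.raises(ValueError):
            local_filter_expected(m, 5, 3, P=1, W=2)
        with pytest.raises(ValueError):
            local_filter_expected(m, 2, 5, P=4, W=3)


class TestCallHic:
    def test_poisson_tail_example(self):
        # P(Pois(2) >= 10)
        assert stats.poisson.sf(9, 2) == pytest.approx(4.6498e-5, rel=1e-3)

    def test_planted_peaks_recovered(self):
        rng = np.random.default_rng(5)
        lam = 10.0
        c = rng.poisson(lam, size=(120, 120))
        planted = [(20, 50), (40, 100), (70, 90)]
        for i, j in planted:
            c[i, j] = rng.poisson(10 * lam)
        m = ContactMatrix("chr1", 5000, c)
        calls = call_hic(m, P=3, W=6, fdr=0.025)
        got = {(c_.anchor1.start // 5000, c_.anchor2.start // 5000) for c_ in calls}
        assert set(planted) <= got

    def test_homogeneous_null_rarely_calls(self):
        rng = np.random.default_rng(6)
        m = ContactMatrix("chr1", 5000, rng.poisson(8.0, size=(100, 100)))
        assert len(call_hic(m, P=3, W=6, fdr=0.025)) == 0

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            call_hic(ContactMatrix("chr1", 1000, np.full((30, 30), 0.5)))


class TestContactMatrixIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        m = ContactMatrix("chr9", 2000, rng.poisson(3, size=(25, 25)))
        path = tmp_path / "m.txt"
        write_contact_matrix(path, m)
        back = read_contact_matrix(path)
        assert back.chrom == "chr9" and back.resolution == 2000
        assert np.array_equal(back.counts, m.counts)

    def test_size_limit(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("#chrom=chr1\n#resolution=1000\n0\t50000\t1\n")
        with pytest.raises(ValueError, match="exceeds"):
            read_contact_matrix(path, max_bins=1000)
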