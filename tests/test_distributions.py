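"""Weighted histograms, quantiles, W1, ranking, stratification."""

import numpy as np
import pytest

from fragbench.distributions import (
    BIN_WIDTH,
    ScoredPsm,
    SimilarityDistribution,
    build_distribution,
    combine,
    quantiles,
    rank_methods,
    stratify,
    wasserstein,
)
from fragbench.errors import ConfigError, DataError


def oracle_accumulate(scores, multiplicity, lo, hi, width):
    """Naive loop accumulation, independent of the vectorized path."""
    n_bins = int(round((hi - lo) / width))
    weights = [0.0] * n_bins
    for s, pid in scores:
        k = int((s - lo) / width)
        if k == n_bins:
            k -= 1
        weights[k] += 1.0 / multiplicity[pid]
    return np.array(weights)


def _point_mass(center_bin_lo, lo=0.0, hi=1.0):
    d = SimilarityDistribution(lo, hi)
    d.add(center_bin_lo + BIN_WIDTH / 2)
    return d


class TestBuildDistribution:
    def test_equal_precursor_impact(self):
        scores = [(0.9, "A"), (0.91, "A"), (0.92, "A"), (0.5, "B")]
        d = build_distribution(scores, {"A": 3, "B": 1})
        assert d.total_mass == pytest.approx(2.0)

    def test_single_bin(self):
        scores = [(0.9995, "A"), (0.9995, "B")]
        d = build_distribution(scores, {"A": 1, "B": 1})
        assert (d.weights > 0).sum() == 1
        assert d.weights[999] == pytest.approx(2.0)

    def test_oracle_accumulation(self, rng):
        pids = [f"p{i}" for i in range(50)]
        scores = [(float(rng.random()), pids[int(rng.integers(0, 50))])
                  for _ in range(1000)]
        mult = {}
        for _, pid in scores:
            mult[pid] = mult.get(pid, 0) + 1
        d = build_distribution(scores, mult)
        np.testing.assert_allclose(d.weights, oracle_accumulate(scores, mult, 0, 1, BIN_WIDTH))
        assert d.total_mass == pytest.approx(len(mult))

    def test_top_edge_closed(self):
        d = build_distribution([(1.0, "A")], {"A": 1})
        assert d.weights[-1] == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError, match="outside range"):
            build_distribution([(1.5, "A")], {"A": 1})

    def test_missing_multiplicity_rejected(self):
        with pytest.raises(DataError):
            build_distribution([(0.5, "A")], {})

    def test_literal_weighting_flag(self):
        scores = [(0.9, "A"), (0.9, "A"), (0.5, "B")]
        d = build_distribution(scores, {"A": 2, "B": 1}, literal_weighting=True)
        assert d.total_mass == pytest.approx(2 * 2 + 1)


class TestCombine:
    def test_mass_additive(self, rng):
        d1 = build_distribution([(0.3, "A")], {"A": 1})
        d1.weights *= 2.0
        d2 = build_distribution([(0.7, "B"), (0.7, "C"), (0.8, "D")],
                                {"B": 1, "C": 1, "D": 1})
        assert combine([d1, d2]).total_mass == pytest.approx(5.0)

    def test_identity_with_zero(self):
        d = build_distribution([(0.5, "A")], {"A": 1})
        z = SimilarityDistribution(0.0, 1.0)
        np.testing.assert_array_equal(combine([d, z]).weights, d.weights)

    def test_associative_commutative(self, rng):
        ds = []
        for _ in range(3):
            d = SimilarityDistribution(0.0, 1.0)
            d.weights[:] = rng.random(d.n_bins)
            ds.append(d)
        ab_c = combine([combine(ds[:2]), ds[2]])
        a_bc = combine([ds[0], combine(ds[1:])])
        np.testing.assert_allclose(ab_c.weights, a_bc.weights, atol=1e-12)
        np.testing.assert_allclose(combine(ds[::-1]).weights, ab_c.weights, atol=1e-12)

    def test_mismatched_binning_rejected(self):
        with pytest.raises(DataError):
            combine([SimilarityDistribution(0.0, 1.0), SimilarityDistribution(-1.0, 1.0)])


class TestQuantiles:
    def test_point_mass(self):
        q = quantiles(_point_mass(0.800))
        assert q.q10 == q.q90 == pytest.approx(0.8005)

    def test_two_bin_median_crossing_convention(self):
        d = SimilarityDistribution(0.0, 1.0)
        d.add(0.1005)
        d.add(0.9005)
        q = quantiles(d)
        assert q.median == pytest.approx(0.1005)
        assert q.q75 == pytest.approx(0.9005)

    def test_against_sort_based(self, rng):
        scores = rng.random(10_000)
        d = build_distribution([(float(s), i) for i, s in enumerate(scores)],
                               {i: 1 for i in range(len(scores))})
        q = quantiles(d)
        for got, p in [(q.q10, 0.1), (q.q25, 0.25), (q.median, 0.5),
                       (q.q75, 0.75), (q.q90, 0.9)]:
            exact = np.quantile(scores, p)
            assert abs(got - exact) <= BIN_WIDTH

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            quantiles(SimilarityDistribution(0.0, 1.0))

    def test_monotone(self, rng):
        for _ in range(20):
            d = SimilarityDistribution(0.0, 1.0)
            d.weights[:] = rng.random(d.n_bins)
            q = quantiles(d)
            assert q.q10 <= q.q25 <= q.median <= q.q75 <= q.q90


class TestWasserstein:
    def test_identical_zero(self, rng):
        d = SimilarityDistribution(0.0, 1.0)
        d.weights[:] = rng.random(d.n_bins)
        assert wasserstein(d, d) == 0.0

    def test_point_mass_translation(self):
        assert wasserstein(_point_mass(0.800), _point_mass(0.900)) == \
            pytest.approx(0.100, abs=BIN_WIDTH)

    def test_normalization_before_cdf(self):
        d1 = _point_mass(0.800)
        d2 = _point_mass(0.900)
        d2.weights *= 10.0  # unnormalized mass must not matter
        assert wasserstein(d1, d2) == pytest.approx(0.100, abs=BIN_WIDTH)

    def test_sampling_transport_oracle(self, rng):
        for _ in range(5):
            d1 = SimilarityDistribution(0.0, 1.0)
            d2 = SimilarityDistribution(0.0, 1.0)
            a = rng.integers(0, 950)
            d1.weights[a:a + 50] = rng.random(50)
            b = rng.integers(0, 950)
            d2.weights[b:b + 50] = rng.random(50)
            n = 100_000
            u = (np.arange(n) + 0.5) / n
            s1 = np.searchsorted(np.cumsum(d1.weights) / d1.total_mass, u)
            s2 = np.searchsorted(np.cumsum(d2.weights) / d2.total_mass, u)
            oracle = np.abs(d1.centers[s1] - d2.centers[s2]).mean()
            assert wasserstein(d1, d2) == pytest.approx(oracle, abs=2 * BIN_WIDTH)

    def test_metric_axioms(self, rng):
        ds = []
        for _ in range(3):
            d = SimilarityDistribution(0.0, 1.0)
            d.weights[:] = rng.random(d.n_bins)
            ds.append(d)
        a, b, c = ds
        assert wasserstein(a, b) == pytest.approx(wasserstein(b, a), abs=1e-9)
        assert wasserstein(a, c) <= wasserstein(a, b) + wasserstein(b, c) + 1e-9
        assert wasserstein(a, b) >= 0

    def test_zero_implies_equal_quantiles(self, rng):
        d1 = SimilarityDistribution(0.0, 1.0)
        d1.weights[:] = rng.random(d1.n_bins)
        d2 = d1.copy()
        d2.weights *= 3.0
        assert wasserstein(d1, d2) == pytest.approx(0.0, abs=1e-12)
        q1, q2 = quantiles(d1), quantiles(d2)
        for a, b in zip((q1.q10, q1.median, q1.q90), (q2.q10, q2.median, q2.q90)):
            assert abs(a - b) <= BIN_WIDTH

    def test_uniform_shift_convergence(self, rng):
        """Binned W1 of uniform vs shifted uniform approaches the shift."""
        shift = 0.15
        n = 200_000
        x = rng.uniform(0.1, 0.6, n)
        d1 = SimilarityDistribution(0.0, 1.0)
        d2 = SimilarityDistribution(0.0, 1.0)
        for d, vals in ((d1, x), (d2, x + shift)):
            idx = np.minimum((vals / BIN_WIDTH).astype(int), d.n_bins - 1)
            np.add.at(d.weights, idx, 1.0)
        assert wasserstein(d1, d2) == pytest.approx(shift, abs=3 * BIN_WIDTH)

    def test_empty_rejected(self):
        d = _point_mass(0.5)
        with pytest.raises(DataError):
            wasserstein(d, SimilarityDistribution(0.0, 1.0))


class TestRankMethods:
    def _dist_with_median(self, m):
        d = SimilarityDistribution(0.0, 1.0)
        d.add(m)
        return d

    def test_descending_by_median(self):
        exp = self._dist_with_median(0.95)
        per = {name: (self._dist_with_median(m), exp)
               for name, m in [("M1", 0.9), ("M2", 0.8), ("M3", 0.85)]}
        reports = rank_methods(per)
        assert [(r.method_name, r.rank) for r in reports] == \
            [("M1", 1), ("M3", 2), ("M2", 3)]

    def test_w1_reported(self):
        exp = self._dist_with_median(0.9505)
        reports = rank_methods({"M": (self._dist_with_median(0.8505), exp)})
        assert reports[0].w1_to_experimental == pytest.approx(0.1, abs=BIN_WIDTH)

    def test_tie_broken_by_q75_then_name(self):
        d_hi_q75 = SimilarityDistribution(0.0, 1.0)
        d_hi_q75.add(0.5, 2.0)
        d_hi_q75.add(0.95, 1.0)
        d_lo_q75 = SimilarityDistribution(0.0, 1.0)
        d_lo_q75.add(0.5, 2.0)
        d_lo_q75.add(0.7, 1.0)
        reports = rank_methods({"B": (d_lo_q75, None), "A": (d_hi_q75, None)})
        assert [r.method_name for r in reports] == ["A", "B"]
        same = self._dist_with_median(0.5)
        reports = rank_methods({"Z": (same.copy(), None), "A": (same.copy(), None)})
        assert [r.method_name for r in reports] == ["A", "Z"]

    def test_single_method(self):
        reports = rank_methods({"only": (self._dist_with_median(0.5), None)})
        assert reports[0].rank == 1 and reports[0].w1_to_experimental is None

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            rank_methods({})


def _scored(score, pid, charge=2, length=10, nce=27.0, modified=False):
    return ScoredPsm(score, pid, charge, length, nce, modified)


class TestStratify:
    def test_by_charge(self):
        recs = [_scored(0.9, "A", charge=1), _scored(0.8, "B", charge=2),
                _scored(0.7, "C", charge=2), _scored(0.6, "D", charge=3)]
        strata = stratify(recs, "charge")
        assert set(strata) == {"z=1", "z=2", "z=3"}
        assert strata["z=2"].total_mass == pytest.approx(2.0)

    def test_by_ptm_status(self):
        recs = [_scored(0.9, "A", modified=True), _scored(0.8, "B")]
        strata = stratify(recs, "ptm_status")
        assert strata["modified"].total_mass == pytest.approx(1.0)
        assert strata["unmodified"].total_mass == pytest.approx(1.0)

    def test_length_falls_in_one_bin(self):
        recs = [_scored(0.9, "A", length=12)]
        strata = stratify(recs, "length_bins")
        assert list(strata) == ["len=11-14"]

    def test_partition_conserves_records(self, rng):
        recs = [_scored(float(rng.random()), f"p{i}", charge=int(rng.integers(1, 5)))
                for i in range(100)]
        strata = stratify(recs, "charge")
        # every precursor is unique here, so total mass = record count
        assert sum(d.total_mass for d in strata.values()) == pytest.approx(100.0)

    def test_multiplicity_recomputed_within_stratum(self):
        recs = [_scored(0.9, "A", charge=2), _scored(0.8, "A", charge=2),
                _scored(0.7, "A", charge=3)]
        strata = stratify(recs, "charge")
        # precursor A has 2 PSMs in z=2 and 1 in z=3: each stratum mass 1
        assert strata["z=2"].total_mass == pytest.approx(1.0)
        assert strata["z=3"].total_mass == pytest.approx(1.0)

    def test_unknown_stratifier(self):
        with pytest.raises(ConfigError):
            stratify([_scored(0.5, "A")], "retention_time")


def test_bad_binning_config():
    with pytest.raises(ConfigError):
        SimilarityDistribution(0.0, 1.0005)
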