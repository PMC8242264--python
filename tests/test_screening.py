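from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mlgwas.data_io import GenotypeDataset
from mlgwas.mlm import ScanResult
from mlgwas.screening import (
    CandidateSet,
    dedup_by_radius,
    kw_scan,
    lars_select_per_chromosome,
    select_by_pvalue,
    sis_screen,
)


def _dataset(codes, chroms=None, positions=None):
    codes = np.asarray(codes, float)
    n, m = codes.shape
    info = pd.DataFrame(
        {
            "name": [f"m{j}" for j in range(m)],
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": positions if positions is not None else np.arange(m) * 10_000 + 1,
            "major": ["A"] * m,
            "minor": ["B"] * m,
            "maf": [0.25] * m,
        }
    )
    return GenotypeDataset([f"i{k}" for k in range(n)], info, codes)


def _scan(pvalues):
    p = np.asarray(pvalues, float)
    return ScanResult(np.zeros(len(p)), np.zeros(len(p)), p, method="test")


class TestSelectByPvalue:
    def test_threshold(self):
        cs = select_by_pvalue(_scan([0.001, 0.01, 0.5]), 0.005)
        assert list(cs.indices) == [0]

    def test_all_pass_when_alpha_one(self):
        cs = select_by_pvalue(_scan([0.3, 1.0, 0.9]), 1.0)
        assert len(cs) == 3

    def test_empty_result_allowed(self):
        assert len(select_by_pvalue(_scan([1.0, 1.0]), 0.005)) == 0


class TestDedupByRadius:
    def _cands(self, pvals, positions, chroms=None):
        m = len(pvals)
        info = pd.DataFrame(
            {
                "name": [f"m{j}" for j in range(m)],
                "chrom": chroms if chroms is not None else ["1"] * m,
                "pos": positions,
                "major": ["A"] * m,
                "minor": ["B"] * m,
                "maf": [0.25] * m,
            }
        )
        cs = CandidateSet(
            np.arange(m), method="t",
            pvalues={i: float(pvals[i]) for i in range(m)},
        )
        return cs, info

    def test_close_pair_keeps_smaller_p(self):
        cs, info = self._cands([0.01, 0.001], [10_000, 15_000])
        out = dedup_by_radius(cs, info, 20.0)
        assert list(out.indices) == [1]

    def test_distant_pair_survives(self):
        cs, info = self._cands([0.01, 0.001], [10_000, 35_000])
        out = dedup_by_radius(cs, info, 20.0)
        assert list(out.indices) == [0, 1]

    def test_greedy_sweep_three_markers(self):
        """p increasing with position at 0/15/30 kb: keep the ends."""
        cs, info = self._cands([0.001, 0.01, 0.05], [0, 15_000, 30_000])
        out = dedup_by_radius(cs, info, 20.0)
        assert list(out.indices) == [0, 2]

    def test_chromosomes_independent(self):
        cs, info = self._cands([0.001, 0.002], [10_000, 15_000], ["1", "2"])
        out = dedup_by_radius(cs, info, 20.0)
        assert len(out) == 2

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        pvals=st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12),
        radius=st.floats(1.0, 50.0),
    )
    def test_radius_constraint_never_violated(self, pvals, radius):
        positions = [7_000 * (j + 1) for j in range(len(pvals))]
        cs, info = self._cands(pvals, positions)
        out = dedup_by_radius(cs, info, radius)
        kept_pos = sorted(info["pos"].iloc[out.indices])
        for a, b in zip(kept_pos, kept_pos[1:]):
            assert b - a > radius * 1000


class TestKWScan:
    def test_hand_computed_h(self):
        """y = 1..6 split [-1,-1,-1,+1,+1,+1]: H = 3.857 (no ties)."""
        y = np.array([1.0, 2, 3, 4, 5, 6])
        codes = np.array([[-1], [-1], [-1], [1], [1], [1]], float)
        scan = kw_scan(y, _dataset(codes))
        assert scan.statistics[0] == pytest.approx(3.857142857, abs=1e-6)
        assert scan.pvalues[0] == pytest.approx(stats.chi2.sf(3.857142857, 1), abs=1e-6)

    def test_matches_scipy_kruskal(self, rng):
        """Dual route: vectorized H equals scipy.stats.kruskal per marker."""
        n = 40
        codes = rng.choice([-1.0, 0.0, 1.0], size=(n, 12))
        y = rng.standard_normal(n)
        scan = kw_scan(y, _dataset(codes))
        for j in range(12):
            groups = [y[codes[:, j] == a] for a in (-1, 0, 1)
                      if np.sum(codes[:, j] == a) > 0]
            if len(groups) < 2:
                assert scan.pvalues[j] == 1.0
                continue
            H, p = stats.kruskal(*groups)
            assert scan.statistics[j] == pytest.approx(H, rel=1e-10)
            assert scan.pvalues[j] == pytest.approx(p, rel=1e-10)

    def test_degenerate_all_tied_phenotype(self):
        y = np.ones(10)
        codes = np.tile([[-1.0], [1.0]], (5, 1))
        scan = kw_scan(y, _dataset(codes))
        assert scan.pvalues[0] == 1.0

    def test_single_class_marker(self):
        y = np.arange(8.0)
        codes = np.ones((8, 1))
        scan = kw_scan(y, _dataset(codes))
        assert scan.pvalues[0] == 1.0

    def test_monotone_transform_invariance(self, rng):
        y = rng.standard_normal(30)
        codes = rng.choice([-1.0, 0.0, 1.0], size=(30, 8))
        ds = _dataset(codes)
        s1 = kw_scan(y, ds)
        s2 = kw_scan(np.exp(y / 2) + 5, ds)  # strictly monotone transform
        assert np.allclose(s1.statistics, s2.statistics)
        assert np.allclose(s1.pvalues, s2.pvalues)

    def test_chi2_decision_matches_exact_permutation(self, rng):
        """n = 7 two-class instances: same accept/reject at alpha = 0.05."""
        n = 7
        for _ in range(20):
            n1 = int(rng.integers(2, 6))
            labels = np.array([-1.0] * n1 + [1.0] * (n - n1))
            y = rng.standard_normal(n)
            scan = kw_scan(y, _dataset(labels[:, None]))
            p_chi2 = scan.pvalues[0]
            h_obs = scan.statistics[0]
            # exhaustive permutation over all class assignments
            count = total = 0
            for idx in combinations(range(n), n1):
                lab = np.full(n, 1.0)
                lab[list(idx)] = -1.0
                h = kw_scan(y, _dataset(lab[:, None])).statistics[0]
                count += h >= h_obs - 1e-12
                total += 1
            p_exact = count / total
            assert (p_chi2 <= 0.05) == (p_exact <= 0.05)


class TestLars:
    def test_single_correlated_marker_enters_first(self, rng):
        n = 40
        codes = rng.choice([-1.0, 0.0, 1.0], size=(n, 5))
        y = 2.0 * codes[:, 3] + 0.1 * rng.standard_normal(n)
        cs = lars_select_per_chromosome(y, _dataset(codes), max_per_chrom=1)
        assert list(cs.indices) == [3]

    def test_orthonormal_entry_order_is_correlation_order(self, rng):
        """On an orthonormal design LAR entry order = descending |x'y|."""
        n, m = 50, 20
        A = rng.standard_normal((n, m + 1))
        A[:, 0] = 1.0
        Q, _ = np.linalg.qr(A)
        Z = Q[:, 1:]  # orthonormal, zero-mean columns
        y = rng.standard_normal(n)
        ds = _dataset(np.zeros((n, m)))
        cs = lars_select_per_chromosome(y, ds, max_per_chrom=m, Z=Z)
        order_stat = sorted(cs.statistics, key=lambda j: cs.statistics[j])
        Zs = (Z - Z.mean(0)) / Z.std(0)
        expected = list(np.argsort(-np.abs(Zs.T @ (y - y.mean()))))
        assert order_stat == expected[: len(order_stat)]

    def test_max_per_chrom_respected(self, rng):
        codes = rng.choice([-1.0, 0.0, 1.0], size=(30, 10))
        y = rng.standard_normal(30)
        cs = lars_select_per_chromosome(y, _dataset(codes), max_per_chrom=2)
        assert len(cs) == 2

    def test_chromosomes_selected_independently(self, rng):
        codes = rng.choice([-1.0, 0.0, 1.0], size=(30, 10))
        chroms = ["1"] * 5 + ["2"] * 5
        y = rng.standard_normal(30)
        cs = lars_select_per_chromosome(
            y, _dataset(codes, chroms=chroms), max_per_chrom=2
        )
        assert len(cs) == 4


class TestSIS:
    def test_causal_marker_ranked_first(self, rng):
        n, m = 100, 30
        hits = 0
        for _ in range(25):
            codes = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
            y = 1.5 * codes[:, 7] + 0.5 * rng.standard_normal(n)
            cs = sis_screen(y, _dataset(codes), d=1, iterations=1)
            hits += list(cs.indices) == [7]
        assert hits >= 24

    def test_dimension_respected(self, rng):
        codes = rng.choice([-1.0, 0.0, 1.0], size=(30, 10))
        y = rng.standard_normal(30)
        cs = sis_screen(y, _dataset(codes), d=3, iterations=1)
        assert len(cs) == 3

    def test_d_not_smaller_than_m_warns_and_keeps_all(self, rng):
        codes = rng.choice([-1.0, 0.0, 1.0], size=(30, 5))
        y = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="keeping all"):
            cs = sis_screen(y, _dataset(codes), d=10)
        assert len(cs) == 5

    def test_duplicate_marker_tie_breaks_to_lower_index(self, rng):
        codes = rng.choice([-1.0, 0.0, 1.0], size=(50, 6))
        codes[:, 4] = codes[:, 1]  # exact duplicate
        y = codes[:, 1] + 0.1 * rng.standard_normal(50)
        cs = sis_screen(y, _dataset(codes), d=1, iterations=1)
        assert list(cs.indices) == [1]

    def test_iterations_extend_the_set(self, rng):
        n, m = 80, 40
        codes = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
        y = codes[:, 3] - codes[:, 30] + 0.3 * rng.standard_normal(n)
        cs = sis_screen(y, _dataset(codes), d=2, iterations=2)
        assert len(cs) == 4
        assert {3, 30} <= set(cs.indices)
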