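"""Cortical asymmetry index: density estimation, JSD, and the CAI contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortasym.atlas import DESIKAN_KILLIANY_REGIONS, N_REGIONS
from cortasym.cai import (
    CAIConfig,
    DiscreteDistribution,
    compute_cai,
    estimate_density,
    jensen_shannon_distance,
    pooled_support,
)
from cortasym.cohort import RegionalThicknessProfile


def brute_force_jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Independent oracle: JS distance from the KL-divergence definition.

    JS(p,q) = 0.5 KL(p||m) + 0.5 KL(q||m) with m = (p+q)/2, logs base 2;
    the distance is its square root. Written directly from the divergence
    sums rather than the entropy identity the implementation uses.
    """
    m = 0.5 * (p + q)
    kl_pm = sum(pi * np.log2(pi / mi) for pi, mi in zip(p, m) if pi > 0)
    kl_qm = sum(qi * np.log2(qi / mi) for qi, mi in zip(q, m) if qi > 0)
    return float(np.sqrt(0.5 * kl_pm + 0.5 * kl_qm))


def _dist(mass, lo=2.0, hi=3.0):
    mass = np.asarray(mass, dtype=float)
    edges = np.linspace(lo, hi, mass.size + 1)
    return DiscreteDistribution(edges, mass)


def _profile(pid, hemi, values, visit=0):
    return RegionalThicknessProfile(pid, visit, hemi, DESIKAN_KILLIANY_REGIONS,
                                    np.asarray(values, dtype=float))


class TestEstimateDensity:
    def test_point_mass_lands_in_one_bin(self):
        cfg = CAIConfig(n_bins=8)
        d = estimate_density(np.full(34, 2.5), cfg, (2.0, 3.0))
        assert d.mass.max() > 1 - 8 * cfg.smoothing_epsilon
        # 2.5 sits on the edge between bins 3 and 4 of [2,3]/8; histogram
        # assigns it to the right-closed bin 4
        assert d.mass.argmax() == 4

    def test_uniform_grid_two_bins_split_evenly(self):
        values = np.linspace(2.0, 3.0, 34)
        cfg = CAIConfig(n_bins=2, smoothing_epsilon=1e-12)
        d = estimate_density(values, cfg, (2.0, 3.0))
        np.testing.assert_allclose(d.mass, [17 / 34, 17 / 34], atol=1e-9)

    @given(st.lists(st.floats(1.5, 3.5), min_size=34, max_size=34),
           st.sampled_from(["histogram", "gaussian_kde"]))
    @settings(max_examples=40, deadline=None)
    def test_masses_sum_to_one(self, values, estimator):
        cfg = CAIConfig(estimator=estimator)
        d = estimate_density(np.array(values), cfg, (1.0, 4.0))
        assert abs(d.mass.sum() - 1.0) < 1e-12

    def test_value_outside_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            estimate_density(np.full(34, 5.0), CAIConfig(), (2.0, 3.0))


class TestJensenShannonDistance:
    def test_identical_distributions_give_zero(self):
        p = _dist([0.25, 0.25, 0.25, 0.25])
        assert jensen_shannon_distance(p, p) == 0.0

    def test_disjoint_supports_give_one(self):
        assert jensen_shannon_distance(_dist([1, 0]), _dist([0, 1])) == 1.0

    def test_hand_computed_value(self):
        # H(0.75, 0.25) = 0.8112781245 bits; sqrt(H(m) - 0.5) = 0.5579...
        got = jensen_shannon_distance(_dist([0.5, 0.5]), _dist([1, 0]))
        assert got == pytest.approx(0.5579230452841438, abs=1e-10)

    def test_mismatched_edges_rejected(self):
        with pytest.raises(ValueError, match="bin edges"):
            jensen_shannon_distance(_dist([1, 0], 2.0, 3.0), _dist([1, 0], 2.0, 3.1))

    def test_matches_brute_force_oracle_on_random_pairs(self, rng):
        for _ in range(1000):
            p = rng.dirichlet(np.ones(16))
            q = rng.dirichlet(np.ones(16))
            got = jensen_shannon_distance(_dist(p, 2, 3), _dist(q, 2, 3))
            assert got == pytest.approx(brute_force_jsd(p, q), abs=1e-10)
            # symmetry, boundedness
            assert got == jensen_shannon_distance(_dist(q, 2, 3), _dist(p, 2, 3))
            assert 0.0 <= got <= 1.0


class TestComputeCAI:
    def test_identical_hemispheres_give_zero(self, rng):
        vals = rng.uniform(2, 3, N_REGIONS)
        res = compute_cai(_profile("A", "left", vals), _profile("A", "right", vals))
        assert res.cai <= 1e-12

    def test_hemisphere_swap_invariance(self, rng):
        left = _profile("A", "left", rng.uniform(2, 3, N_REGIONS))
        right = _profile("A", "right", rng.uniform(2, 3, N_REGIONS))
        assert compute_cai(left, right).cai == compute_cai(right, left).cai

    def test_same_hemisphere_twice_rejected(self, rng):
        a = _profile("A", "left", rng.uniform(2, 3, N_REGIONS))
        b = _profile("A", "left", rng.uniform(2, 3, N_REGIONS))
        with pytest.raises(ValueError, match="left"):
            compute_cai(a, b)

    def test_mismatched_participant_rejected(self, rng):
        a = _profile("A", "left", rng.uniform(2, 3, N_REGIONS))
        b = _profile("B", "right", rng.uniform(2, 3, N_REGIONS))
        with pytest.raises(ValueError, match="participant"):
            compute_cai(a, b)

    def test_offset_profile_matches_independent_computation(self, rng):
        """CAI of (L, L + 0.5mm) equals a from-scratch histogram+JSD computation."""
        vals = rng.uniform(2.0, 2.8, N_REGIONS)
        left = _profile("A", "left", vals)
        right = _profile("A", "right", vals + 0.5)
        cfg = CAIConfig(n_bins=16)
        got = compute_cai(left, right, cfg).cai

        # independent reconstruction: pooled support, half-bin padding,
        # epsilon-smoothed histograms, KL-form JSD
        lo = min(vals.min(), (vals + 0.5).min())
        hi = max(vals.max(), (vals + 0.5).max())
        pad = (hi - lo) / 16 / 2
        edges = np.linspace(lo - pad, hi + pad, 17)
        hl, _ = np.histogram(vals, bins=edges)
        hr, _ = np.histogram(vals + 0.5, bins=edges)
        p = hl + cfg.smoothing_epsilon
        q = hr + cfg.smoothing_epsilon
        p, q = p / p.sum(), q / q.sum()
        assert got == pytest.approx(brute_force_jsd(p, q), abs=1e-10)

    def test_region_relabelling_invariance(self, rng):
        """Permuting both profiles' region order identically leaves CAI unchanged."""
        vals_l = rng.uniform(2, 3, N_REGIONS)
        vals_r = rng.uniform(2, 3, N_REGIONS)
        perm = rng.permutation(N_REGIONS)
        regions_p = tuple(DESIKAN_KILLIANY_REGIONS[i] for i in perm)
        base = compute_cai(_profile("A", "left", vals_l), _profile("A", "right", vals_r)).cai
        permuted = compute_cai(
            RegionalThicknessProfile("A", 0, "left", regions_p, vals_l[perm]),
            RegionalThicknessProfile("A", 0, "right", regions_p, vals_r[perm]),
        ).cai
        assert permuted == base

    def test_monotone_response_to_left_thinning(self, rng):
        """Mean CAI strictly increases with a uniform left-thinning offset."""
        offsets = (0.0, 0.05, 0.1, 0.2)
        means = []
        for delta in offsets:
            cais = []
            for i in range(100):
                base = rng.normal(2.5, 0.25, N_REGIONS)
                noise_l = rng.normal(0, 0.05, N_REGIONS)
                noise_r = rng.normal(0, 0.05, N_REGIONS)
                left = _profile(f"S{i}", "left", np.clip(base - delta + noise_l, 0.5, None))
                right = _profile(f"S{i}", "right", np.clip(base + noise_r, 0.5, None))
                cais.append(compute_cai(left, right).cai)
            means.append(np.mean(cais))
        assert all(a < b for a, b in zip(means, means[1:])), means

    def test_kde_estimator_runs_and_bounds(self, rng):
        cfg = CAIConfig(estimator="gaussian_kde")
        left = _profile("A", "left", rng.uniform(2, 3, N_REGIONS))
        right = _profile("A", "right", rng.uniform(2, 3, N_REGIONS))
        assert 0.0 <= compute_cai(left, right, cfg).cai <= 1.0

    def test_degenerate_pooled_range_widens(self):
        cfg = CAIConfig()
        lo, hi = pooled_support(np.full(34, 2.5), np.full(34, 2.5), cfg)
        assert lo < 2.5 < hi
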