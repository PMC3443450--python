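import itertools

import numpy as np
import pytest

from canemap.segregation import filter_sdm
from canemap.simulate import haldane_rf
from canemap.twopoint import (
    COUPLING,
    REPULSION,
    PhaseConfig,
    admissible_phases,
    all_pairs,
    estimate_pair,
    joint_pattern_probs,
    pair_class,
    pattern_counts,
)
from tests.conftest import simulate_chain

CLASSES = [
    ("D1", "D1"), ("D2", "D2"), ("C", "C"),
    ("D1", "C"), ("C", "D1"), ("D2", "C"), ("C", "D2"),
]


def oracle_probs(cross_a, cross_b, phase, r):
    """Brute-force enumeration over the 16 joint transmission outcomes.

    Locus A uses reference phases (0, 0); locus B carries the relative
    phase (coupling keeps the reference homolog, repulsion swaps it).
    Each parent recombines between the loci independently with
    probability r; initial transmissions are uniform.
    """
    def band(cross, a, b, pa, pb):
        if cross == "D1":
            return int(a == pa)
        if cross == "D2":
            return int(b == pb)
        return int(a == pa or b == pb)

    pa = 1 if phase.phase_p1 == REPULSION else 0
    pb = 1 if phase.phase_p2 == REPULSION else 0
    out = {(1, 1): 0.0, (1, 0): 0.0, (0, 1): 0.0, (0, 0): 0.0}
    for a1, b1 in itertools.product((0, 1), repeat=2):
        for ra, rb in itertools.product((0, 1), repeat=2):
            p = 0.25 * (r if ra else 1 - r) * (r if rb else 1 - r)
            a2, b2 = a1 ^ ra, b1 ^ rb
            out[(band(cross_a, a1, b1, 0, 0), band(cross_b, a2, b2, pa, pb))] += p
    return out


class TestJointPatternProbs:
    @pytest.mark.parametrize("cross_a,cross_b", CLASSES)
    def test_matches_enumeration_oracle(self, cross_a, cross_b):
        rng = np.random.default_rng(2024)
        for r in rng.uniform(0, 0.5, size=50):
            for phase in admissible_phases(cross_a, cross_b):
                got = joint_pattern_probs(cross_a, cross_b, phase, float(r))
                want = oracle_probs(cross_a, cross_b, phase, float(r))
                for pat in got:
                    assert got[pat] == pytest.approx(want[pat], abs=1e-12)
                assert sum(got.values()) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("cross_a,cross_b", CLASSES)
    def test_marginals_conserved(self, cross_a, cross_b):
        """Marginal segregation (1:1 or 3:1) is independent of linkage."""
        for r in (0.0, 0.123, 0.35, 0.5):
            for phase in admissible_phases(cross_a, cross_b):
                p = joint_pattern_probs(cross_a, cross_b, phase, r)
                marg_a = p[(1, 1)] + p[(1, 0)]
                marg_b = p[(1, 1)] + p[(0, 1)]
                assert marg_a == pytest.approx(0.75 if cross_a == "C" else 0.5)
                assert marg_b == pytest.approx(0.75 if cross_b == "C" else 0.5)

    def test_independence_at_half(self):
        for cross_a, cross_b in CLASSES:
            for phase in admissible_phases(cross_a, cross_b):
                p = joint_pattern_probs(cross_a, cross_b, phase, 0.5)
                ma = p[(1, 1)] + p[(1, 0)]
                mb = p[(1, 1)] + p[(0, 1)]
                assert p[(1, 1)] == pytest.approx(ma * mb, abs=1e-12)

    def test_cxc_coupling_at_zero(self):
        phase = PhaseConfig(COUPLING, COUPLING)
        p = joint_pattern_probs("C", "C", phase, 0.0)
        assert p[(1, 1)] == pytest.approx(0.75)
        assert p[(0, 0)] == pytest.approx(0.25)
        assert p[(1, 0)] == p[(0, 1)] == 0.0

    def test_r_out_of_range(self):
        with pytest.raises(ValueError):
            joint_pattern_probs("D1", "D1", PhaseConfig(COUPLING, None), 0.6)


class TestEstimatePair:
    def test_d1xd1_coupling_closed_form(self):
        est = estimate_pair((40, 10, 10, 40), "D1", "D1")
        assert est.best_phase.phase_p1 == COUPLING
        assert est.rf_hat == pytest.approx(0.2, abs=1e-9)

    def test_d1xd1_repulsion_same_rf(self):
        est = estimate_pair((10, 40, 40, 10), "D1", "D1")
        assert est.best_phase.phase_p1 == REPULSION
        assert est.rf_hat == pytest.approx(0.2, abs=1e-9)

    def test_d1xd2_noninformative(self):
        est = estimate_pair((50, 40, 45, 53), "D1", "D2")
        assert not est.informative
        assert est.rf_hat is None

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            estimate_pair((0, 0, 0, 0), "D1", "D1")

    @pytest.mark.parametrize("cross_a,cross_b", CLASSES)
    def test_matches_grid_oracle(self, cross_a, cross_b):
        """The phase-wise ML solve is at least as good as a dense r grid."""
        rng = np.random.default_rng(5)
        grid = np.linspace(1e-6, 0.5, 2001)
        for _ in range(5):
            counts = tuple(int(x) for x in rng.integers(1, 80, size=4))
            est = estimate_pair(counts, cross_a, cross_b)
            best_grid = -np.inf
            for phase in admissible_phases(cross_a, cross_b):
                for r in grid:
                    probs = joint_pattern_probs(cross_a, cross_b, phase, float(r))
                    ll = sum(
                        n * np.log(probs[pat])
                        for pat, n in zip([(1, 1), (1, 0), (0, 1), (0, 0)], counts)
                        if n
                    )
                    best_grid = max(best_grid, ll)
            assert est.loglik_at_hat >= best_grid - 1e-6

    @pytest.mark.parametrize("cross_a,cross_b", CLASSES)
    def test_symmetry_under_transpose(self, cross_a, cross_b):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n11, n10, n01, n00 = (int(x) for x in rng.integers(1, 60, size=4))
            a = estimate_pair((n11, n10, n01, n00), cross_a, cross_b)
            b = estimate_pair((n11, n01, n10, n00), cross_b, cross_a)
            assert a.rf_hat == pytest.approx(b.rf_hat, abs=1e-9)
            assert a.lod == pytest.approx(b.lod, abs=1e-9)

    def test_lod_nonnegative_random_counts(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            counts = tuple(int(x) for x in rng.integers(0, 60, size=4))
            if sum(counts) == 0:
                continue
            est = estimate_pair(counts, "D1", "C")
            assert est.lod >= 0.0
            assert 0.0 <= est.rf_hat <= 0.5

    def test_null_pairs_have_small_lod(self):
        """Independent markers (r = 0.5) rarely reach even LOD 1."""
        rng = np.random.default_rng(123)
        n = 188
        low = 0
        sims = 500
        for _ in range(sims):
            a = rng.random(n) < 0.5
            b = rng.random(n) < 0.5
            counts = (
                int((a & b).sum()), int((a & ~b).sum()),
                int((~a & b).sum()), int((~a & ~b).sum()),
            )
            est = estimate_pair(counts, "D1", "D1")
            low += est.lod < 1.0
        assert low >= 0.95 * sims


class TestAllPairs:
    def test_three_markers_three_pairs(self, toy_table):
        results, _ = filter_sdm(toy_table, alpha_global=1e-9)
        estimates = all_pairs(results, toy_table)
        assert len(estimates) == 3
        classes = {e.pair_class for e in estimates}
        assert "D1xD2" in classes  # present but flagged noninformative
        noninf = [e for e in estimates if e.pair_class == "D1xD2"]
        assert all(not e.informative for e in noninf)

    def test_adjacent_rf_recovery_n188(self):
        """Adjacent-pair rf within +/-0.05 of truth on a 20-marker chromosome."""
        crosses = (["D1", "C", "D2", "D1", "C"] * 4)[:20]
        table, ids, *_ = simulate_chain(31, crosses, spacing_cm=10.0, n=188)
        results, _ = filter_sdm(table, alpha_global=1e-9)
        estimates = {
            frozenset((e.marker_a, e.marker_b)): e
            for e in all_pairs(results, table)
        }
        true_rf = haldane_rf(10.0)
        errors = []
        for a, b in zip(ids[:-1], ids[1:]):
            est = estimates[frozenset((a, b))]
            if est.informative:
                errors.append(est.rf_hat - true_rf)
        errors = np.array(errors)
        assert len(errors) >= 12
        # C-involved pairs have estimator SD ~0.04 at n=188, so the +/-0.05
        # band holds for the estimator, not every single draw
        assert np.mean(np.abs(errors)) < 0.035
        assert np.mean(np.abs(errors) <= 0.05) >= 0.8
        assert abs(errors.mean()) < 0.02  # unbiased

    def test_missing_dropped_pairwise(self):
        table, ids, *_ = simulate_chain(
            8, ["D1", "D1"], spacing_cm=5.0, n=100, missing_rate=0.2
        )
        results, _ = filter_sdm(table, alpha_global=1e-9)
        est = all_pairs(results, table)[0]
        counts = pattern_counts(table.records[0].scores, table.records[1].scores)
        assert est.n == sum(counts.values()) < 100


def test_pair_class_symmetry():
    for ca, cb in CLASSES + [("D1", "D2"), ("D2", "D1")]:
        assert pair_class(ca, cb) == pair_class(cb, ca)
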