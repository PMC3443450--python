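import math

import numpy as np
import pytest

from canemap.segregation import filter_sdm
from canemap.simulate import haldane_rf
from canemap.twopoint import (
    COUPLING,
    REPULSION,
    all_pairs,
    joint_pattern_probs,
    pattern_counts,
)
from canemap import multipoint as mp
from canemap.multipoint import (
    GroupData,
    OrderingConfig,
    assign_phases,
    compare_orders,
    hmm_loglik,
    kosambi,
    kosambi_inv,
    order_group,
    order_seq,
    refine_phases,
    ripple,
)
from tests.conftest import simulate_chain


class TestKosambi:
    def test_zero(self):
        assert kosambi(0.0) == 0.0

    def test_quarter(self):
        assert kosambi(0.25) == pytest.approx(27.465307, abs=1e-3)

    def test_round_trip(self):
        for r in (0.0, 0.05, 0.1, 0.25, 0.4, 0.49):
            assert kosambi_inv(kosambi(r)) == pytest.approx(r, abs=1e-12)

    def test_strictly_increasing_and_above_naive(self):
        rs = np.linspace(0.0, 0.49, 200)
        ds = np.array([kosambi(r) for r in rs])
        assert np.all(np.diff(ds) > 0)
        assert np.all(ds >= 100.0 * rs - 1e-12)

    def test_half_errors(self):
        with pytest.raises(ValueError):
            kosambi(0.5)


class TestHmmTwoPointEquivalence:
    """For 2 loci the HMM chain likelihood is the two-point multinomial."""

    CASES = [
        ("D1", "D1", (COUPLING, None)),
        ("D1", "D1", (REPULSION, None)),
        ("D2", "D2", (None, COUPLING)),
        ("C", "C", (COUPLING, COUPLING)),
        ("C", "C", (COUPLING, REPULSION)),
        ("C", "C", (REPULSION, REPULSION)),
        ("D1", "C", (COUPLING, None)),
        ("D2", "C", (None, REPULSION)),
        ("D1", "D2", (None, None)),
    ]

    @pytest.mark.parametrize("cross_a,cross_b,rel", CASES)
    def test_equivalence(self, cross_a, cross_b, rel):
        table, ids, *_ = simulate_chain(
            7, [cross_a, cross_b], spacing_cm=15.0, n=60,
            phases=(np.zeros(2, dtype=int), np.zeros(2, dtype=int)),
        )
        counts = pattern_counts(table.records[0].scores, table.records[1].scores)
        rel_p1, rel_p2 = rel
        phase_p1 = {ids[0]: 0, ids[1]: 1 if rel_p1 == REPULSION else 0}
        phase_p2 = {ids[0]: 0, ids[1]: 1 if rel_p2 == REPULSION else 0}
        cross = {ids[0]: cross_a, ids[1]: cross_b}
        rng = np.random.default_rng(99)
        for r in rng.uniform(0.001, 0.5, size=50):
            probs = joint_pattern_probs(cross_a, cross_b, _phase(rel), float(r))
            want = sum(
                n * math.log(probs[pat]) for pat, n in counts.items() if n
            )
            got = hmm_loglik(ids, table, cross, phase_p1, phase_p2, [float(r)])
            assert got == pytest.approx(want, abs=1e-9)

    def test_free_recombination_factorizes(self):
        table, ids, *_ = simulate_chain(3, ["D1", "C", "D2"], n=50)
        cross = {m: c for m, c in zip(ids, ["D1", "C", "D2"])}
        p0 = {m: 0 for m in ids}
        got = hmm_loglik(ids, table, cross, p0, p0, [0.5, 0.5])
        want = 0.0
        for rec, c in zip(table.records, ["D1", "C", "D2"]):
            n1 = int((rec.scores == 1).sum())
            n0 = int((rec.scores == 0).sum())
            p1 = 0.75 if c == "C" else 0.5
            want += n1 * math.log(p1) + n0 * math.log(1 - p1)
        assert got == pytest.approx(want, abs=1e-9)

    def test_all_missing_individual_contributes_zero(self):
        table, ids, *_ = simulate_chain(4, ["D1", "D1"], n=40)
        cross = {m: "D1" for m in ids}
        p0 = {m: 0 for m in ids}
        base = hmm_loglik(ids, table, cross, p0, p0, [0.2])
        for rec in table.records:
            rec.scores = np.append(rec.scores, np.int8(-1))
        table.individuals.append("ghost")
        with_ghost = hmm_loglik(ids, table, cross, p0, p0, [0.2])
        assert with_ghost == pytest.approx(base, abs=1e-12)


def _phase(rel):
    from canemap.twopoint import PhaseConfig

    return PhaseConfig(rel[0], rel[1])


def _group_setup(table, alpha=1e-12):
    results, _ = filter_sdm(table, alpha)
    estimates = {
        frozenset((e.marker_a, e.marker_b)): e for e in all_pairs(results, table)
    }
    cross = {r.marker_id: r.cross_type for r in results}
    return cross, estimates


class TestEM:
    def test_recovers_r_ten_percent(self):
        d = -50.0 * math.log(1.0 - 0.2)  # Haldane distance for r = 0.10
        table, ids, *_ = simulate_chain(
            21, ["D1", "D1"], spacing_cm=d, n=10_000,
            phases=(np.zeros(2, dtype=int), np.zeros(2, dtype=int)),
        )
        cross, estimates = _group_setup(table)
        p1, p2 = assign_phases(ids, cross, estimates)
        data = GroupData(ids, table, cross, p1, p2)
        rfs, ll, conv = data.em([0, 1], np.array([0.3]), maxit=500)
        assert conv
        assert rfs[0] == pytest.approx(0.10, abs=0.01)

    def test_cosegregating_pair_goes_to_zero(self):
        table, ids, *_ = simulate_chain(
            5, ["D1", "D1"], spacing_cm=0.0, n=200,
            phases=(np.zeros(2, dtype=int), np.zeros(2, dtype=int)),
        )
        cross = {m: "D1" for m in ids}
        p0 = {m: 0 for m in ids}
        data = GroupData(ids, table, cross, p0, p0)
        rfs, _, _ = data.em([0, 1], np.array([0.25]), maxit=500)
        assert rfs[0] < 1e-3

    def test_matches_grid_search_oracle_three_markers(self):
        table, ids, *_ = simulate_chain(13, ["D1", "C", "D2"], spacing_cm=12.0, n=188)
        cross, estimates = _group_setup(table)
        p1, p2 = assign_phases(ids, cross, estimates)
        data = GroupData(ids, table, cross, p1, p2)
        rfs, ll, _ = data.em([0, 1, 2], np.array([0.2, 0.2]), maxit=1000, tol=1e-10)
        # 2-D grid oracle over the same likelihood surface
        grid = np.arange(0.005, 0.4, 0.005)
        best = (-np.inf, None)
        for r1 in grid:
            for r2 in grid:
                v = data.loglik([0, 1, 2], np.array([r1, r2]))
                if v > best[0]:
                    best = (v, (r1, r2))
        fine1 = np.arange(best[1][0] - 0.005, best[1][0] + 0.005, 2e-4)
        fine2 = np.arange(best[1][1] - 0.005, best[1][1] + 0.005, 2e-4)
        for r1 in fine1:
            for r2 in fine2:
                v = data.loglik([0, 1, 2], np.array([r1, r2]))
                if v > best[0]:
                    best = (v, (r1, r2))
        assert rfs[0] == pytest.approx(best[1][0], abs=1e-3)
        assert rfs[1] == pytest.approx(best[1][1], abs=1e-3)
        assert ll >= best[0] - 1e-6


class TestOrdering:
    def test_three_marker_order_recovery(self):
        """Exhaustive search finds the true 3-marker order in >=95% of seeds."""
        wins = 0
        for seed in range(100):
            table, ids, *_ = simulate_chain(
                1000 + seed, ["D1", "D1", "D1"], spacing_cm=10.0, n=188
            )
            cross, estimates = _group_setup(table)
            cg = order_group("CG", ids, table, cross, estimates, do_ripple=False)
            wins += cg.markers in (ids, ids[::-1])
        assert wins >= 95

    def test_two_markers_single_order(self):
        table, ids, *_ = simulate_chain(2, ["D1", "D1"], n=50)
        cross, estimates = _group_setup(table)
        cg = order_group("CG", ids, table, cross, estimates)
        assert sorted(cg.markers) == sorted(ids)

    def test_reversal_symmetric_loglik(self):
        table, ids, *_ = simulate_chain(77, ["D1", "C", "D2", "D1"], n=150)
        cross, estimates = _group_setup(table)
        p1, p2 = assign_phases(ids, cross, estimates)
        data = GroupData(ids, table, cross, p1, p2)
        rfs = np.array([0.1, 0.2, 0.15])
        fwd = data.loglik([0, 1, 2, 3], rfs)
        rev = data.loglik([3, 2, 1, 0], rfs[::-1].copy())
        assert fwd == pytest.approx(rev, abs=1e-9)

    def test_order_seq_recovers_seven_collinear_markers(self):
        table, ids, *_ = simulate_chain(
            55, ["D1"] * 7, spacing_cm=12.0, n=188,
            phases=(np.zeros(7, dtype=int), np.zeros(7, dtype=int)),
        )
        cross, estimates = _group_setup(table)
        cg = order_group("CG", ids, table, cross, estimates)
        assert cg.markers in (ids, ids[::-1])
        assert sorted(cg.markers) == sorted(ids)

    def test_order_seq_flags_uninformative_marker(self):
        table, ids, *_ = simulate_chain(
            60, ["D1"] * 7, spacing_cm=12.0, n=188,
        )
        # append an unlinked noise marker: no insertion slot clearly wins
        rng = np.random.default_rng(0)
        noise = rng.integers(0, 2, size=table.n_individuals).astype(np.int8)
        from canemap.io import MarkerRecord, MarkerSystem, PRESENT, ABSENT

        table.records.append(
            MarkerRecord("D1-E99M99999", MarkerSystem.AFLP, PRESENT, ABSENT, noise)
        )
        all_ids = ids + ["D1-E99M99999"]
        cross, estimates = _group_setup(table)
        cg = order_group("CG", all_ids, table, cross, estimates, do_ripple=False)
        assert sorted(cg.markers) == sorted(all_ids)  # everything placed once
        assert "D1-E99M99999" in cg.forced

    def test_ripple_corrects_adjacent_swap(self):
        table, ids, *_ = simulate_chain(
            88, ["D1"] * 5, spacing_cm=15.0, n=188,
            phases=(np.zeros(5, dtype=int), np.zeros(5, dtype=int)),
        )
        cross, estimates = _group_setup(table)
        p1, p2 = assign_phases(ids, cross, estimates)
        data = GroupData(ids, table, cross, p1, p2)
        from canemap.multipoint import OrderedCG, _build_ordered, _twopoint_lookup

        tw = _twopoint_lookup(estimates)
        cfg = OrderingConfig()
        swapped = [0, 2, 1, 3, 4]
        bad = _build_ordered("CG", data, swapped, tw, cfg)
        fixed = ripple(bad, data, estimates, config=cfg)
        assert fixed.markers in (ids, ids[::-1])
        assert fixed.loglik >= bad.loglik

    def test_ripple_keeps_optimal_order(self):
        table, ids, *_ = simulate_chain(
            91, ["D1"] * 4, spacing_cm=20.0, n=188,
            phases=(np.zeros(4, dtype=int), np.zeros(4, dtype=int)),
        )
        cross, estimates = _group_setup(table)
        p1, p2 = assign_phases(ids, cross, estimates)
        data = GroupData(ids, table, cross, p1, p2)
        from canemap.multipoint import _build_ordered, _twopoint_lookup

        tw = _twopoint_lookup(estimates)
        cfg = OrderingConfig()
        good = _build_ordered("CG", data, [0, 1, 2, 3], tw, cfg)
        same = ripple(good, data, estimates, config=cfg)
        assert same.markers == good.markers


class TestPhaseRefinement:
    def test_wrong_phase_detected_and_fixed(self):
        table, ids, *_ = simulate_chain(
            33, ["D1", "C", "D1", "C", "D1"], spacing_cm=10.0, n=188
        )
        cross, estimates = _group_setup(table)
        p1, p2 = assign_phases(ids, cross, estimates)
        data = GroupData(ids, table, cross, p1, p2)
        from canemap.multipoint import _twopoint_lookup

        tw = _twopoint_lookup(estimates)
        cfg = OrderingConfig()
        order = list(range(5))
        ll_clean, flips_clean = refine_phases(data, order, tw, cfg)
        # sabotage: flip one C marker's phase in parent 2
        data.flip_phase(1, 2)
        ll_fixed, flips = refine_phases(data, order, tw, cfg)
        assert flips >= 1
        assert ll_fixed == pytest.approx(ll_clean, abs=1e-4)


def test_em_loglik_monotone_by_construction():
    """The EM assertion guard would raise on any decrease; a normal fit runs."""
    table, ids, *_ = simulate_chain(3, ["D1", "C", "D2", "C"], n=100)
    cross, estimates = _group_setup(table)
    p1, p2 = assign_phases(ids, cross, estimates)
    data = GroupData(ids, table, cross, p1, p2)
    rfs, ll, conv = data.em(
        [0, 1, 2, 3], np.array([0.3, 0.05, 0.45]), maxit=300
    )
    assert np.all((rfs >= 0) & (rfs <= 0.5))
    assert np.isfinite(ll)
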