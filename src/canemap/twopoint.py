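"""Two-point recombination fraction, linkage phase and LOD for marker pairs.

Model
-----
For two single-dose dominant loci, each F1 individual is described by the
pair of parental transmissions ``(a, b)``: which of parent 1's two homologs
and which of parent 2's was passed at the locus.  Between the two loci each
parent is recombinant independently with probability ``r`` (one shared
``r`` per pair, the integrated-map convention).  Band presence maps onto
transmissions through the cross type (D1: band iff the P1 homolog carrying
the allele is transmitted; D2 analogous for P2; C: either parent suffices),
so the joint distribution of the four band patterns ``(1,1) (1,0) (0,1)
(0,0)`` is a closed-form function of ``r`` and of the relative linkage
phase within each informative parent (coupling: band alleles on the same
homolog; repulsion: on opposite homologs).

The maximum-likelihood ``r`` and phase are found per pair; the LOD score is
``log10 L(r_hat, phase) - log10 L(0.5)``.  A D1 x D2 pair carries no
two-point linkage information (its two bands ride on independent parental
transmissions), which is why simplex-by-simplex C loci are needed as
bridges between the two parental marker sets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .io import ABSENT, PRESENT, MarkerTable
from .segregation import CROSS_C, CROSS_D1, CROSS_D2, SegregationResult

COUPLING = "coupling"
REPULSION = "repulsion"

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class PhaseConfig:
    """Relative pair phase per parent; ``None`` where a parent is uninformative."""

    phase_p1: str | None
    phase_p2: str | None


@dataclass
class PairEstimate:
    marker_a: str
    marker_b: str
    pair_class: str            # e.g. "D1xD1", "D1xC", "D1xD2"
    informative: bool
    rf_hat: float | None
    best_phase: PhaseConfig | None
    loglik_at_hat: float | None
    lod: float | None
    n: int


def pair_class(cross_a: str, cross_b: str) -> tuple[str, bool]:
    """Canonical class label and informativeness of a cross-type pair."""
    key = frozenset((cross_a, cross_b))
    if key == frozenset((CROSS_D1, CROSS_D2)):
        return "D1xD2", False
    label = {
        frozenset((CROSS_D1,)): "D1xD1",
        frozenset((CROSS_D2,)): "D2xD2",
        frozenset((CROSS_C,)): "CxC",
        frozenset((CROSS_D1, CROSS_C)): "D1xC",
        frozenset((CROSS_D2, CROSS_C)): "D2xC",
    }[key]
    return label, True


def admissible_phases(cross_a: str, cross_b: str) -> list[PhaseConfig]:
    """Phase configurations consistent with which parents are doubly heterozygous."""
    p1_inf = cross_a in (CROSS_D1, CROSS_C) and cross_b in (CROSS_D1, CROSS_C)
    p2_inf = cross_a in (CROSS_D2, CROSS_C) and cross_b in (CROSS_D2, CROSS_C)
    opts1 = (COUPLING, REPULSION) if p1_inf else (None,)
    opts2 = (COUPLING, REPULSION) if p2_inf else (None,)
    return [PhaseConfig(a, b) for a, b in itertools.product(opts1, opts2)]


def _q(phase: str, r: float) -> float:
    # probability that the informative parent's transmission at locus B
    # matches the band-phase of locus A's allele
    return 1.0 - r if phase == COUPLING else r


def joint_pattern_probs(
    cross_a: str, cross_b: str, phase: PhaseConfig, r: float
) -> dict[tuple[int, int], float]:
    """P(band_a, band_b) over {1,0}^2 for a marker pair at recombination ``r``."""
    if not 0.0 <= r <= 0.5:
        raise ValueError("r must lie in [0, 0.5]")
    key = (cross_a, cross_b)
    if key in ((CROSS_D1, CROSS_D1), (CROSS_D2, CROSS_D2)):
        ph = phase.phase_p1 if cross_a == CROSS_D1 else phase.phase_p2
        q = _q(ph, r)
        p11 = p00 = q / 2.0
        p10 = p01 = (1.0 - q) / 2.0
    elif key == (CROSS_C, CROSS_C):
        m = _q(phase.phase_p1, r) * _q(phase.phase_p2, r)
        p11 = (2.0 + m) / 4.0
        p10 = p01 = (1.0 - m) / 4.0
        p00 = m / 4.0
    elif key in ((CROSS_D1, CROSS_C), (CROSS_D2, CROSS_C)):
        ph = phase.phase_p1 if key[0] == CROSS_D1 else phase.phase_p2
        q = _q(ph, r)
        p11 = (1.0 + q) / 4.0
        p10 = (1.0 - q) / 4.0
        p01 = (2.0 - q) / 4.0
        p00 = q / 4.0
    elif key in ((CROSS_C, CROSS_D1), (CROSS_C, CROSS_D2)):
        sw = joint_pattern_probs(key[1], key[0], phase, r)
        return {(a, b): sw[(b, a)] for (a, b) in sw}
    elif key in ((CROSS_D1, CROSS_D2), (CROSS_D2, CROSS_D1)):
        p11 = p10 = p01 = p00 = 0.25
    else:
        raise ValueError(f"unknown cross-type pair {key}")
    return {(1, 1): p11, (1, 0): p10, (0, 1): p01, (0, 0): p00}


def _loglik(counts, probs) -> float:
    ll = 0.0
    for pat, n in counts.items():
        if n:
            p = probs[pat]
            if p <= 0.0:
                return -math.inf
            ll += n * math.log(p)
    return ll


def _solve_concave(score, lo: float, hi: float, iters: int = 80) -> float:
    """Bisection root of a decreasing score function on (lo, hi)."""
    if score(lo + 1e-12) <= 0.0:
        return lo
    if score(hi - 1e-12) >= 0.0:
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if score(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _mle_for_phase(counts, cross_a, cross_b, phase) -> tuple[float, float]:
    """Constrained ML over r in [0, 0.5] for one phase; returns (r_hat, loglik)."""
    n11, n10, n01, n00 = (
        counts[(1, 1)], counts[(1, 0)], counts[(0, 1)], counts[(0, 0)]
    )
    key = (cross_a, cross_b)
    if key in ((CROSS_C, CROSS_D1), (CROSS_C, CROSS_D2)):
        sw = {(1, 1): n11, (1, 0): n01, (0, 1): n10, (0, 0): n00}
        return _mle_for_phase(sw, key[1], key[0], phase)
    N = n11 + n10 + n01 + n00
    if key in ((CROSS_D1, CROSS_D1), (CROSS_D2, CROSS_D2)):
        ph = phase.phase_p1 if cross_a == CROSS_D1 else phase.phase_p2
        q_hat = (n11 + n00) / N
        q_hat = min(max(q_hat, 0.5), 1.0) if ph == COUPLING else min(q_hat, 0.5)
        r_hat = 1.0 - q_hat if ph == COUPLING else q_hat
    elif key in ((CROSS_D1, CROSS_C), (CROSS_D2, CROSS_C)):
        ph = phase.phase_p1 if cross_a == CROSS_D1 else phase.phase_p2

        def score(q):
            return (n11 / (1.0 + q) - n10 / (1.0 - q)
                    - n01 / (2.0 - q) + n00 / q)

        q_hat = _solve_concave(score, 0.0, 1.0)
        q_hat = min(max(q_hat, 0.5), 1.0) if ph == COUPLING else min(q_hat, 0.5)
        r_hat = 1.0 - q_hat if ph == COUPLING else q_hat
    elif key == (CROSS_C, CROSS_C):
        def score(m):
            return n11 / (2.0 + m) - (n10 + n01) / (1.0 - m) + n00 / m

        m_hat = _solve_concave(score, 0.0, 1.0)
        pa, pb = phase.phase_p1, phase.phase_p2
        if pa == COUPLING and pb == COUPLING:
            m_hat = max(m_hat, 0.25)                 # r in [0, 0.5] <=> m >= 1/4
            r_hat = 1.0 - math.sqrt(m_hat)
        elif pa == REPULSION and pb == REPULSION:
            m_hat = min(m_hat, 0.25)
            r_hat = math.sqrt(m_hat)
        else:                                        # mixed: m = r(1-r) <= 1/4
            m_hat = min(m_hat, 0.25)
            r_hat = 0.5 * (1.0 - math.sqrt(max(0.0, 1.0 - 4.0 * m_hat)))
    else:
        raise ValueError(f"no two-point information for {key}")
    r_hat = min(max(r_hat, 0.0), 0.5)
    ll = _loglik(counts, joint_pattern_probs(cross_a, cross_b, phase, r_hat))
    return r_hat, ll


def estimate_pair(
    counts: dict[tuple[int, int], int] | tuple[int, int, int, int],
    cross_a: str,
    cross_b: str,
    marker_a: str = "A",
    marker_b: str = "B",
) -> PairEstimate:
    """ML recombination fraction, phase and LOD for one marker pair.

    ``counts`` is the 2x2 band-pattern table (n11, n10, n01, n00) with the
    first index marker A.  Phase ties at equal likelihood break toward
    coupling (repulsion-phase linkage is rarely detectable across the
    homologs of a polyploid, so coupling is the field prior).
    """
    if not isinstance(counts, dict):
        n11, n10, n01, n00 = counts
        counts = {(1, 1): n11, (1, 0): n10, (0, 1): n01, (0, 0): n00}
    N = sum(counts.values())
    if N < 1:
        raise ValueError("no jointly scored individuals")
    label, informative = pair_class(cross_a, cross_b)
    if not informative:
        return PairEstimate(marker_a, marker_b, label, False, None, None, None, None, N)
    best = None
    for phase in admissible_phases(cross_a, cross_b):
        r_hat, ll = _mle_for_phase(counts, cross_a, cross_b, phase)
        if best is None or ll > best[1] + 1e-12:
            best = (r_hat, ll, phase)
    r_hat, ll, phase = best
    ll_null = _loglik(
        counts, joint_pattern_probs(cross_a, cross_b, phase, 0.5)
    )
    lod = max(0.0, (ll - ll_null) / _LN10)
    return PairEstimate(marker_a, marker_b, label, True, r_hat, phase, ll, lod, N)


def pattern_counts(
    scores_a: np.ndarray, scores_b: np.ndarray
) -> dict[tuple[int, int], int]:
    """Joint band-pattern counts over pairwise-complete individuals."""
    ok = (scores_a != -1) & (scores_b != -1)
    a = scores_a[ok] == PRESENT
    b = scores_b[ok] == PRESENT
    return {
        (1, 1): int(np.sum(a & b)),
        (1, 0): int(np.sum(a & ~b)),
        (0, 1): int(np.sum(~a & b)),
        (0, 0): int(np.sum(~a & ~b)),
    }


def all_pairs(
    results: list[SegregationResult], table: MarkerTable
) -> list[PairEstimate]:
    """Two-point estimates for every unordered pair of kept markers.

    Individuals missing either marker of a pair are dropped for that pair
    only (pairwise-complete observations).  Pattern counts for all pairs
    are obtained by integer matrix products, so the full quadratic sweep
    stays fast at map scale.
    """
    kept = [r for r in results if r.kept]
    if len(kept) < 2:
        raise ValueError("need at least 2 kept markers")
    by_id = {rec.marker_id: rec for rec in table.records}
    ids = [r.marker_id for r in kept]
    cross = {r.marker_id: r.cross_type for r in kept}
    S = np.stack([by_id[i].scores for i in ids])
    P = (S == PRESENT).astype(np.int32)
    Ab = (S == ABSENT).astype(np.int32)
    n11 = P @ P.T
    n10 = P @ Ab.T
    n01 = Ab @ P.T
    n00 = Ab @ Ab.T
    out: list[PairEstimate] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            counts = {
                (1, 1): int(n11[i, j]), (1, 0): int(n10[i, j]),
                (0, 1): int(n01[i, j]), (0, 0): int(n00[i, j]),
            }
            if sum(counts.values()) == 0:
                continue
            out.append(
                estimate_pair(counts, cross[ids[i]], cross[ids[j]], ids[i], ids[j])
            )
    return out
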