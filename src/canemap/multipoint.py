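"""Multipoint ordering of co-segregation groups via a 4-state HMM.

The hidden state at a locus is the pair ``(a, b)`` of parental
transmissions (which P1 homolog and which P2 homolog the individual
received), relative to a fixed phase reference.  Between adjacent loci the
transition factorizes over the two independent meioses,
``t(a,a'; r) * t(b,b'; r)`` with ``t = 1-r`` when the homolog is retained
and ``r`` when recombined, one shared ``r`` per interval.  Emissions are
deterministic given the cross type and the marker's linkage phase
(D1 emits a band iff ``a`` equals the band-carrying homolog, D2 via ``b``,
C via either; missing observations emit 1), so dominant single-dose data
from both parents are integrated in one likelihood.

Interval recombination fractions are fitted by Baum-Welch EM (the E-step
counts expected recombinations per interval per parent, the M-step divides
by twice the number of individuals); marker order is searched by exhaustive
comparison for small groups, frame-plus-sequential-insertion for larger
ones, and a sliding-window ``ripple`` polish.  Fitted fractions are
converted to map distances with the Kosambi function
``d = 25 ln((1+2r)/(1-2r))`` cM.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import MISSING, PRESENT, MarkerTable
from .segregation import CROSS_C, CROSS_D1, CROSS_D2
from .twopoint import COUPLING, PairEstimate

_LN10 = math.log(10.0)


def kosambi(r: float) -> float:
    """Map distance in cM for recombination fraction ``r`` (interference-aware)."""
    if r < 0.0 or r >= 0.5:
        raise ValueError("r must lie in [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_inv(d_cm: float) -> float:
    """Inverse Kosambi: recombination fraction for a distance in cM."""
    if d_cm < 0.0:
        raise ValueError("distance must be >= 0")
    return 0.5 * math.tanh(d_cm / 50.0)


@dataclass(frozen=True)
class OrderingConfig:
    exhaustive_max: int = 6
    frame_size: int = 5
    ripple_window: int = 4
    em_tol: float = 1e-6
    em_maxit: int = 200
    search_em_maxit: int = 15     # EM cap while comparing candidate orders
    # small groups get full-precision comparisons: their candidate sets are
    # cheap and near-tied orders need converged likelihoods to rank reliably
    small_group_size: int = 9
    search_em_maxit_small: int = 60
    insertion_lod_threshold: float = 3.0

    def __post_init__(self):
        if min(self.exhaustive_max, self.frame_size, self.ripple_window,
               self.em_maxit, self.search_em_maxit) < 1 or self.em_tol <= 0:
            raise ValueError("ordering parameters must be positive")


@dataclass
class OrderedCG:
    """A co-segregation group with fitted order, phases and interval rfs."""

    name: str
    markers: list[str]
    cross_types: dict[str, str]
    phase_p1: dict[str, int]
    phase_p2: dict[str, int]
    rfs: np.ndarray
    loglik: float
    converged: bool = True
    forced: list[str] = field(default_factory=list)

    @property
    def positions_cm(self) -> np.ndarray:
        d = [kosambi(min(float(r), 0.4999999)) for r in self.rfs]
        return np.concatenate([[0.0], np.cumsum(d)])

    @property
    def length_cm(self) -> float:
        return float(self.positions_cm[-1]) if len(self.markers) > 1 else 0.0


# ---------------------------------------------------------------------------
# phase assignment

def assign_phases(
    markers: list[str],
    cross_types: dict[str, str],
    estimates: dict[frozenset, PairEstimate],
) -> tuple[dict[str, int], dict[str, int]]:
    """Absolute band-carrying homolog (0/1) per marker per parent.

    Relative two-point phases are propagated along a maximum-LOD spanning
    tree of the markers informative in each parent (coupling: same
    homolog; repulsion: opposite), with an arbitrary root fixed at 0.
    Uninformative parents get 0; the value never enters the likelihood.
    """
    phases: list[dict[str, int]] = []
    for parent in (1, 2):
        inform_types = (CROSS_D1, CROSS_C) if parent == 1 else (CROSS_D2, CROSS_C)
        nodes = [m for m in markers if cross_types[m] in inform_types]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                est = estimates.get(frozenset((a, b)))
                if est is None or not est.informative or est.best_phase is None:
                    continue
                rel = est.best_phase.phase_p1 if parent == 1 else est.best_phase.phase_p2
                if rel is None:
                    continue
                g.add_edge(a, b, weight=est.lod, flip=0 if rel == COUPLING else 1)
        ph = {m: 0 for m in markers}
        for comp in nx.connected_components(g):
            tree = nx.maximum_spanning_tree(g.subgraph(comp))
            root = sorted(comp)[0]
            for parent_node, child in nx.bfs_edges(tree, root):
                ph[child] = ph[parent_node] ^ tree[parent_node][child]["flip"]
        phases.append(ph)
    return phases[0], phases[1]


# ---------------------------------------------------------------------------
# HMM core

_STATE_A = np.array([0, 0, 1, 1])
_STATE_B = np.array([0, 1, 0, 1])
_MASK_A = (_STATE_A[:, None] != _STATE_A[None, :]).astype(float)
_MASK_B = (_STATE_B[:, None] != _STATE_B[None, :]).astype(float)
_N_DIFF = _MASK_A + _MASK_B  # recombination events separating two states


def _transition(r: float) -> np.ndarray:
    ta = np.array([[1.0 - r, r], [r, 1.0 - r]])
    return np.kron(ta, ta)


def _transitions_batch(rfs: np.ndarray) -> np.ndarray:
    """(..., 4, 4) transition matrices for an array of interval rfs."""
    r = rfs[..., None, None]
    return (1.0 - r) ** (2.0 - _N_DIFF) * r ** _N_DIFF


class GroupData:
    """Per-group emission cache shared by all candidate orders."""

    def __init__(
        self,
        markers: list[str],
        table: MarkerTable,
        cross_types: dict[str, str],
        phase_p1: dict[str, int],
        phase_p2: dict[str, int],
    ):
        self.markers = list(markers)
        self.cross_types = cross_types
        self.phase_p1 = dict(phase_p1)
        self.phase_p2 = dict(phase_p2)
        by_id = {rec.marker_id: rec for rec in table.records}
        self._scores = [by_id[m].scores for m in markers]
        self.n = table.n_individuals
        self.E = np.ones((self.n, len(markers), 4))
        for l in range(len(markers)):
            self.E[:, l, :] = self._emission_column(l)

    def _band_states(self, l: int, p1: int, p2: int) -> np.ndarray:
        cross = self.cross_types[self.markers[l]]
        if cross == CROSS_D1:
            return _STATE_A == p1
        if cross == CROSS_D2:
            return _STATE_B == p2
        return (_STATE_A == p1) | (_STATE_B == p2)

    def _emission_column(
        self, l: int, p1: int | None = None, p2: int | None = None
    ) -> np.ndarray:
        m = self.markers[l]
        band = self._band_states(
            l,
            self.phase_p1[m] if p1 is None else p1,
            self.phase_p2[m] if p2 is None else p2,
        )
        scores = self._scores[l]
        col = np.ones((self.n, 4))
        pres = scores == PRESENT
        miss = scores == MISSING
        col[pres, :] = band.astype(float)
        col[~pres & ~miss, :] = (~band).astype(float)
        return col

    def column_with_flip(self, l: int, parent: int) -> np.ndarray:
        """Emission column of locus ``l`` with its phase in ``parent`` flipped."""
        m = self.markers[l]
        if parent == 1:
            return self._emission_column(l, p1=1 - self.phase_p1[m])
        return self._emission_column(l, p2=1 - self.phase_p2[m])

    def flip_phase(self, l: int, parent: int) -> None:
        m = self.markers[l]
        if parent == 1:
            self.phase_p1[m] = 1 - self.phase_p1[m]
        else:
            self.phase_p2[m] = 1 - self.phase_p2[m]
        self.E[:, l, :] = self._emission_column(l)

    def loglik(self, order: list[int], rfs: np.ndarray) -> float:
        """Scaled forward-algorithm log-likelihood, uniform initial state."""
        E = self.E[:, order, :]
        alpha = 0.25 * E[:, 0, :]
        c = alpha.sum(axis=1)
        ll = float(np.log(c).sum())
        alpha = alpha / c[:, None]
        for l in range(1, len(order)):
            alpha = (alpha @ _transition(float(rfs[l - 1]))) * E[:, l, :]
            c = alpha.sum(axis=1)
            ll += float(np.log(c).sum())
            alpha = alpha / c[:, None]
        return ll

    def em(
        self,
        order: list[int],
        init_rfs: np.ndarray,
        tol: float = 1e-6,
        maxit: int = 200,
    ) -> tuple[np.ndarray, float, bool]:
        """Baum-Welch fit of interval rfs for a fixed order and phases.

        The per-interval M-step is (expected P1 recombinants + expected P2
        recombinants) / (2N); the log-likelihood is non-decreasing across
        iterations.  Returns (rfs, loglik, converged).
        """
        rfs, lls, conv = self.em_batch(
            [order], np.asarray(init_rfs, dtype=float)[None, :], tol=tol, maxit=maxit
        )
        return rfs[0], float(lls[0]), bool(conv[0])

    def loglik_batch(self, orders: list[list[int]], rfs: np.ndarray) -> np.ndarray:
        """Forward log-likelihood of many orders at one shared rf vector."""
        L = len(orders[0])
        E = np.stack([self.E[:, o, :] for o in orders])
        T = _transitions_batch(np.asarray(rfs, dtype=float))
        a = 0.25 * E[:, :, 0, :]
        c = a.sum(axis=2)
        ll = np.log(c).sum(axis=1)
        a = a / c[..., None]
        for l in range(1, L):
            a = np.einsum("bns,st->bnt", a, T[l - 1]) * E[:, :, l, :]
            c = a.sum(axis=2)
            ll += np.log(c).sum(axis=1)
            a = a / c[..., None]
        return ll

    def em_batch(
        self,
        orders: list[list[int]],
        init_rfs: np.ndarray,
        tol: float = 1e-6,
        maxit: int = 200,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """EM over a batch of candidate orders simultaneously.

        All orders must have the same length; ``init_rfs`` is (B, L-1).
        Candidate-order search (exhaustive comparison, insertion scans,
        ripple windows) calls this with the whole candidate set at once so
        the forward-backward passes stay vectorized over orders as well as
        individuals.  Returns (rfs (B, L-1), logliks (B,), converged (B,)).
        """
        B = len(orders)
        L = len(orders[0])
        if L == 1:
            ll = np.array([self.loglik(o, np.empty(0)) for o in orders])
            return np.empty((B, 0)), ll, np.ones(B, bool)
        E = np.stack([self.E[:, o, :] for o in orders])         # (B, n, L, 4)
        return self._em_core(E, init_rfs, tol, maxit)

    def _em_core(
        self, E: np.ndarray, init_rfs: np.ndarray, tol: float, maxit: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        B, n, L, _ = E.shape
        rfs = np.clip(np.asarray(init_rfs, dtype=float), 1e-4, 0.49)
        prev_ll = np.full(B, -np.inf)
        ll = prev_ll
        converged = np.zeros(B, bool)
        for _ in range(maxit):
            T = _transitions_batch(rfs)                         # (B, L-1, 4, 4)
            alphas = np.empty((L, B, n, 4))
            cs = np.empty((L, B, n))
            a = 0.25 * E[:, :, 0, :]
            cs[0] = a.sum(axis=2)
            alphas[0] = a / cs[0][..., None]
            for l in range(1, L):
                a = np.einsum("bns,bst->bnt", alphas[l - 1], T[:, l - 1])
                a *= E[:, :, l, :]
                cs[l] = a.sum(axis=2)
                alphas[l] = a / cs[l][..., None]
            ll = np.log(cs).sum(axis=(0, 2))                    # (B,)
            betas_next = np.ones((B, n, 4))
            new_rfs = np.empty_like(rfs)
            # backward pass fused with the per-interval E-step; the expected
            # recombination count is sum_{s,t} alpha_s T_st n_diff_st beta'_t
            # (the normalizer of the joint posterior is exactly c_{l+1})
            for l in range(L - 2, -1, -1):
                tmp = E[:, :, l + 1, :] * betas_next            # (B, n, 4)
                tmpn = tmp / cs[l + 1][..., None]
                u = np.einsum("bns,bst->bnt", alphas[l], T[:, l] * _N_DIFF)
                e_rec = (u * tmpn).sum(axis=(1, 2))             # P1 + P2 events
                new_rfs[:, l] = e_rec / (2.0 * n)
                betas_next = np.einsum("bnt,bst->bns", tmpn, T[:, l])
            rfs = np.clip(new_rfs, 1e-6, 0.4999)
            if np.any(ll < prev_ll - 1e-6):
                raise AssertionError("EM log-likelihood decreased")
            converged = np.abs(ll - prev_ll) < tol
            if converged.all():
                break
            prev_ll = ll
        # one forward pass at the returned rfs so loglik matches them
        T = _transitions_batch(rfs)
        a = 0.25 * E[:, :, 0, :]
        c = a.sum(axis=2)
        ll = np.log(c).sum(axis=1)
        a = a / c[..., None]
        for l in range(1, L):
            a = np.einsum("bns,bst->bnt", a, T[:, l - 1]) * E[:, :, l, :]
            c = a.sum(axis=2)
            ll += np.log(c).sum(axis=1)
            a = a / c[..., None]
        return rfs, ll, converged


# ---------------------------------------------------------------------------
# ordering

def _init_rfs(
    order_markers: list[str], twopoint_rf: dict[frozenset, float]
) -> np.ndarray:
    rfs = []
    for a, b in zip(order_markers[:-1], order_markers[1:]):
        r = twopoint_rf.get(frozenset((a, b)), 0.25)
        rfs.append(min(max(r, 1e-4), 0.49))
    return np.array(rfs)


def _twopoint_lookup(
    estimates: dict[frozenset, PairEstimate],
) -> dict[frozenset, float]:
    return {
        k: est.rf_hat
        for k, est in estimates.items()
        if est.informative and est.rf_hat is not None
    }


def _fit_order(
    data: GroupData,
    order: list[int],
    twopoint_rf: dict[frozenset, float],
    config: OrderingConfig,
    final: bool = False,
) -> tuple[np.ndarray, float, bool]:
    names = [data.markers[i] for i in order]
    init = _init_rfs(names, twopoint_rf)
    maxit = config.em_maxit if final else config.search_em_maxit
    return data.em(order, init, tol=config.em_tol, maxit=maxit)


def _fit_orders(
    data: GroupData,
    orders: list[list[int]],
    twopoint_rf: dict[frozenset, float],
    config: OrderingConfig,
) -> np.ndarray:
    """Search-mode batched EM over candidate orders; returns logliks (B,)."""
    inits = np.stack(
        [_init_rfs([data.markers[i] for i in o], twopoint_rf) for o in orders]
    )
    maxit = (
        config.search_em_maxit_small
        if len(orders[0]) <= config.small_group_size
        else config.search_em_maxit
    )
    _, lls, _ = data.em_batch(orders, inits, tol=config.em_tol, maxit=maxit)
    return lls


def _build_ordered(
    name: str,
    data: GroupData,
    order: list[int],
    twopoint_rf: dict[frozenset, float],
    config: OrderingConfig,
    forced: list[str] | None = None,
) -> OrderedCG:
    rfs, ll, conv = _fit_order(data, order, twopoint_rf, config, final=True)
    names = [data.markers[i] for i in order]
    return OrderedCG(
        name=name,
        markers=names,
        cross_types={m: data.cross_types[m] for m in names},
        phase_p1={m: data.phase_p1[m] for m in names},
        phase_p2={m: data.phase_p2[m] for m in names},
        rfs=rfs,
        loglik=ll,
        converged=conv,
        forced=forced or [],
    )


def compare_orders(
    data: GroupData,
    twopoint_rf: dict[frozenset, float],
    config: OrderingConfig = OrderingConfig(),
    name: str = "CG",
) -> OrderedCG:
    """Exhaustive multipoint order search for groups of few markers.

    Evaluates all n!/2 orientation-unique permutations with EM-fitted
    interval rfs and keeps the highest likelihood; exact ties break toward
    the lexicographically smallest index order.
    """
    L = len(data.markers)
    if L > config.exhaustive_max:
        raise ValueError(
            f"{L} markers exceed exhaustive_max={config.exhaustive_max}; "
            "use order_seq"
        )
    perms = [
        perm for perm in itertools.permutations(range(L))
        if perm[0] <= perm[-1]  # drop orientation duplicates
    ]
    lls = _fit_orders(data, [list(p) for p in perms], twopoint_rf, config)
    best_ll = float(lls.max())
    best = min(p for p, ll in zip(perms, lls) if ll >= best_ll - 1e-9)
    return _build_ordered(name, data, list(best), twopoint_rf, config)


def order_seq(
    data: GroupData,
    estimates: dict[frozenset, PairEstimate],
    config: OrderingConfig = OrderingConfig(),
    name: str = "CG",
) -> OrderedCG:
    """Frame-then-insert ordering for groups too large to search exhaustively.

    A seed frame of the most LOD-connected markers is ordered exhaustively;
    remaining markers are inserted one at a time at their likelihood-best
    position.  A marker whose best and second-best insertion likelihoods
    differ by less than ``insertion_lod_threshold`` log10 units is deferred
    and force-inserted (and flagged) after the confident ones — the "safe
    ordering" behaviour of sequential map builders.
    """
    twopoint_rf = _twopoint_lookup(estimates)
    L = len(data.markers)
    total_lod = {m: 0.0 for m in data.markers}
    for i, a in enumerate(data.markers):
        for b in data.markers[i + 1:]:
            est = estimates.get(frozenset((a, b)))
            if est is not None and est.informative and est.lod is not None:
                total_lod[a] += est.lod
                total_lod[b] += est.lod
    ranked = sorted(data.markers, key=lambda m: (-total_lod[m], m))
    frame_names = sorted(ranked[: min(config.frame_size, L)])
    frame_idx = [data.markers.index(m) for m in frame_names]

    sub = _subset_data(data, frame_idx)
    frame_cg = compare_orders(sub, twopoint_rf, config, name=name)
    order = [data.markers.index(m) for m in frame_cg.markers]

    rest = [data.markers.index(m) for m in ranked if data.markers.index(m) not in order]
    deferred: list[int] = []
    threshold = config.insertion_lod_threshold * _LN10

    def best_insertion(cur: list[int], idx: int):
        cands = [cur[:pos] + [idx] + cur[pos:] for pos in range(len(cur) + 1)]
        lls = _fit_orders(data, cands, twopoint_rf, config)
        scored = sorted(zip(lls.tolist(), range(len(cands))), key=lambda t: -t[0])
        return scored

    for idx in rest:
        scored = best_insertion(order, idx)
        if len(scored) > 1 and scored[0][0] - scored[1][0] < threshold:
            deferred.append(idx)
        else:
            pos = scored[0][1]
            order = order[:pos] + [idx] + order[pos:]
    forced_names = []
    for idx in deferred:
        scored = best_insertion(order, idx)
        pos = scored[0][1]
        order = order[:pos] + [idx] + order[pos:]
        forced_names.append(data.markers[idx])
    return _build_ordered(name, data, order, twopoint_rf, config, forced=forced_names)


def _subset_data(data: GroupData, idx: list[int]) -> GroupData:
    sub = GroupData.__new__(GroupData)
    sub.markers = [data.markers[i] for i in idx]
    sub.cross_types = data.cross_types
    sub.phase_p1 = data.phase_p1
    sub.phase_p2 = data.phase_p2
    sub._scores = [data._scores[i] for i in idx]
    sub.E = data.E[:, idx, :]
    sub.n = data.n
    return sub


def refine_phases(
    data: GroupData,
    order: list[int],
    twopoint_rf: dict[frozenset, float],
    config: OrderingConfig,
    max_flips: int = 50,
) -> tuple[float, int]:
    """Post-hoc per-marker linkage-phase re-check on a fixed order.

    The phases propagated from two-point estimates can be wrong for weakly
    anchored markers (typically a C marker whose phase in one parent has no
    strong pairwise support); a wrong phase shows up as a spuriously free
    interval around the marker.  Every admissible single-marker flip is
    refitted (batched) and the best strict improvement accepted, repeating
    until no flip helps.  Mutates ``data`` phases in place; returns the
    final log-likelihood and the number of flips accepted.
    """
    names = [data.markers[i] for i in order]
    init = _init_rfs(names, twopoint_rf)
    maxit = (
        config.search_em_maxit_small
        if len(order) <= config.small_group_size
        else config.search_em_maxit
    )
    _, ll, _ = data.em(order, init, tol=config.em_tol, maxit=maxit)
    cands: list[tuple[int, int]] = []
    for pos, mi in enumerate(order):
        cross = data.cross_types[data.markers[mi]]
        parents = {CROSS_D1: (1,), CROSS_D2: (2,)}.get(cross, (1, 2))
        for parent in parents:
            cands.append((pos, parent))
    base_E = data.E[:, order, :]
    n_flips = 0
    for _ in range(max_flips):
        Es = np.repeat(base_E[None], len(cands), axis=0)
        for k, (pos, parent) in enumerate(cands):
            Es[k, :, pos, :] = data.column_with_flip(order[pos], parent)
        inits = np.repeat(init[None], len(cands), axis=0)
        _, lls, _ = data._em_core(Es, inits, tol=config.em_tol, maxit=maxit)
        k = int(np.argmax(lls))
        if lls[k] <= ll + 1e-6:
            break
        pos, parent = cands[k]
        data.flip_phase(order[pos], parent)
        ll = float(lls[k])
        n_flips += 1
        base_E = data.E[:, order, :]
    return ll, n_flips


def ripple(
    ordered: OrderedCG,
    data: GroupData,
    estimates: dict[frozenset, PairEstimate],
    window: int | None = None,
    config: OrderingConfig = OrderingConfig(),
) -> OrderedCG:
    """Sliding-window permutation polish; accepts strict likelihood gains.

    Every permutation of each length-``window`` window is refitted; any
    strict improvement is adopted and scanning repeats until a full pass
    changes nothing, so the likelihood never decreases.
    """
    if window is None:
        window = config.ripple_window
    twopoint_rf = _twopoint_lookup(estimates)
    order = [data.markers.index(m) for m in ordered.markers]
    L = len(order)
    w = min(window, L)
    maxit = (
        config.search_em_maxit_small
        if L <= config.small_group_size
        else config.search_em_maxit
    )
    best_rfs, best_ll, _ = data.em(
        order, _init_rfs([data.markers[i] for i in order], twopoint_rf),
        tol=config.em_tol, maxit=config.em_maxit,
    )
    improved = True
    while improved:
        improved = False
        for start in range(0, L - w + 1):
            segment = order[start:start + w]
            cands = [
                order[:start] + list(perm) + order[start + w:]
                for perm in itertools.permutations(segment)
                if list(perm) != segment
            ]
            # screen all window permutations with a single forward pass at
            # the incumbent rfs, then EM-refit only the most promising few
            # (warm-started: candidates differ only locally)
            screen = data.loglik_batch(cands, best_rfs)
            top = np.argsort(screen)[::-1][:4]
            shortlist = [cands[int(i)] for i in top]
            inits = np.repeat(best_rfs[None], len(shortlist), axis=0)
            rfs_c, lls, _ = data.em_batch(
                shortlist, inits, tol=config.em_tol, maxit=maxit
            )
            k = int(np.argmax(lls))
            if lls[k] > best_ll + 1e-9:
                order = shortlist[k]
                best_ll = float(lls[k])
                best_rfs = rfs_c[k]
                improved = True
    return _build_ordered(
        ordered.name, data, order, twopoint_rf, config, forced=list(ordered.forced)
    )


def order_group(
    name: str,
    markers: list[str],
    table: MarkerTable,
    cross_types: dict[str, str],
    estimates: dict[frozenset, PairEstimate],
    config: OrderingConfig = OrderingConfig(),
    do_ripple: bool = True,
) -> OrderedCG:
    """Full ordering stack for one co-segregation group.

    Assigns phases from two-point estimates, runs the exhaustive or
    sequential search depending on group size, then the ripple polish.
    """
    p1, p2 = assign_phases(markers, cross_types, estimates)
    data = GroupData(markers, table, cross_types, p1, p2)
    twopoint_rf = _twopoint_lookup(estimates)
    if len(markers) <= config.exhaustive_max:
        cg = compare_orders(data, twopoint_rf, config, name=name)
    else:
        cg = order_seq(data, estimates, config, name=name)
    order = [data.markers.index(m) for m in cg.markers]
    # alternate phase re-checks with ripple polishing until both are stable:
    # a wrong phase can fake a wrong order and vice versa
    ripple_changed = True
    for _ in range(3):
        if len(markers) <= 2:
            break
        _, n_flips = refine_phases(data, order, twopoint_rf, config)
        if not do_ripple or (n_flips == 0 and not ripple_changed):
            break
        polished = ripple(cg, data, estimates, config=config)
        new_order = [data.markers.index(m) for m in polished.markers]
        ripple_changed = new_order != order
        cg, order = polished, new_order
        if not ripple_changed and n_flips == 0:
            break
    return _build_ordered(name, data, order, twopoint_rf, config,
                          forced=list(cg.forced))


def hmm_loglik(
    markers: list[str],
    table: MarkerTable,
    cross_types: dict[str, str],
    phase_p1: dict[str, int],
    phase_p2: dict[str, int],
    rfs,
) -> float:
    """Forward log-likelihood of a fixed order, phases and interval rfs."""
    if not markers:
        raise ValueError("empty marker order")
    rfs = np.asarray(rfs, dtype=float)
    if np.any((rfs < 0) | (rfs > 0.5)):
        raise ValueError("rfs must lie in [0, 0.5]")
    data = GroupData(markers, table, cross_types, phase_p1, phase_p2)
    return data.loglik(list(range(len(markers))), rfs)


def em_rfs(
    markers: list[str],
    table: MarkerTable,
    cross_types: dict[str, str],
    phase_p1: dict[str, int],
    phase_p2: dict[str, int],
    init_rfs,
    config: OrderingConfig = OrderingConfig(),
) -> tuple[np.ndarray, float, bool]:
    """EM-fitted interval rfs for a fixed order (functional wrapper)."""
    data = GroupData(markers, table, cross_types, phase_p1, phase_p2)
    return data.em(
        list(range(len(markers))),
        np.asarray(init_rfs, dtype=float),
        tol=config.em_tol,
        maxit=config.em_maxit,
    )
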