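"""Retrotransposon marker distribution analyses.

Three questions about element-anchored (here *scIvana_1*-derived) markers
on a finished map:

* are they randomly spread?  The map is cut into 10 cM bins and the counts
  of target markers per bin are tested against the Poisson law
  ``P(x) = lambda^x e^-lambda / x!`` (lambda = mean markers per bin) with a
  chi-square goodness-of-fit on the count classes, ``df = c - 1 - 1``
  (``c`` classes, one estimated parameter);
* where are the clusters?  Maximal runs of >= 2 adjacent target markers
  with every gap strictly below 5 cM (intervening markers of other systems
  ignored);
* how many copies does the element have?  Total anchored fragments divided
  by the number of enzyme/primer combinations that produced them — each
  combination samples the same set of genomic copies, so the per-
  combination mean estimates the copy number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .linkagemap import LinkageMap


@dataclass
class PoissonFitResult:
    bin_cm: float
    n_bins: int
    lambda_hat: float
    observed: np.ndarray      # counts of bins with x = 0..x_max markers
    expected: np.ndarray      # n_bins * Poisson pmf(x; lambda_hat)
    chi2: float
    df: int
    p_value: float


@dataclass
class TECluster:
    cg_name: str
    markers: list[str]
    span_cm: float

    @property
    def n_members(self) -> int:
        return len(self.markers)


@dataclass
class CopyNumberEstimate:
    total_fragments: int
    n_combinations: int

    @property
    def estimate_raw(self) -> float:
        return self.total_fragments / self.n_combinations

    @property
    def estimate_rounded(self) -> int:
        return math.floor(self.estimate_raw + 0.5)  # half-up


def _positions_by_group(
    linkage_map: LinkageMap, target_system: str
) -> list[tuple[float, list[float]]]:
    out = []
    for cg in linkage_map.ordered_cgs:
        pos = cg.positions_cm
        targets = [
            float(p)
            for m, p in zip(cg.markers, pos)
            if linkage_map.system_of.get(m) == target_system
        ]
        out.append((cg.length_cm, targets))
    return out


def bin_positions(
    groups: list[tuple[float, list[float]]],
    bin_cm: float = 10.0,
    scope: str = "per_cg",
) -> np.ndarray:
    """Counts per ``bin_cm`` bin for (group length, target positions) pairs.

    Bins restart at 0 in every group, half-open ``[k*bin, (k+1)*bin)``; a
    trailing partial bin counts as one bin.  ``whole_map`` concatenates
    groups end to end first.
    """
    if scope == "whole_map":
        offset = 0.0
        merged: list[float] = []
        for length, targets in groups:
            merged.extend(offset + p for p in targets)
            offset += length
        groups = [(offset, merged)]
    elif scope != "per_cg":
        raise ValueError(f"unknown binning scope {scope!r}")
    counts: list[int] = []
    for length, targets in groups:
        n_bins = max(1, math.ceil(length / bin_cm)) if length > 0 else 1
        c = np.zeros(n_bins, dtype=int)
        for p in targets:
            idx = min(int(p // bin_cm), n_bins - 1)
            c[idx] += 1
        counts.extend(c.tolist())
    return np.asarray(counts, dtype=int)


def bin_markers(
    linkage_map: LinkageMap,
    target_system: str = "RT",
    bin_cm: float = 10.0,
    scope: str = "per_cg",
) -> np.ndarray:
    """Target-system marker counts in ``bin_cm`` bins laid along the map."""
    if not linkage_map.ordered_cgs:
        raise ValueError("empty map")
    return bin_positions(
        _positions_by_group(linkage_map, target_system), bin_cm, scope
    )


def _poisson_chi2(counts: np.ndarray) -> float:
    n = counts.size
    lam = counts.mean()
    x_max = int(counts.max())
    observed = np.bincount(counts, minlength=x_max + 1)
    expected = n * stats.poisson.pmf(np.arange(x_max + 1), lam)
    return float(((observed - expected) ** 2 / expected).sum())


def poisson_gof(
    counts: np.ndarray,
    pool_sparse: bool = False,
    method: str = "chi2",
    n_boot: int = 999,
    seed: int = 0,
) -> PoissonFitResult:
    """Goodness of fit of per-bin counts to a Poisson law.

    ``lambda`` is the mean count per bin; classes run 0..max observed with
    no pooling by default, and the default p-value comes from the
    chi-square distribution with ``df = c - 1 - 1``.  Two refinements are
    available for sparse configurations, where that reference distribution
    is anticonservative (tail classes with tiny expected counts):
    ``pool_sparse`` merges trailing classes until every expected count
    reaches 1, and ``method="bootstrap"`` keeps the unpooled statistic but
    draws its null distribution by parametric simulation at the fitted
    ``lambda`` (``n_boot`` replicates), which restores nominal size without
    the power cost of pooling.
    """
    counts = np.asarray(counts, dtype=int)
    n_bins = counts.size
    if n_bins == 0:
        raise ValueError("no bins")
    lam = float(counts.mean())
    x_max = int(counts.max())
    classes = np.arange(x_max + 1)
    observed = np.array([(counts == x).sum() for x in classes], dtype=float)
    expected = n_bins * stats.poisson.pmf(classes, lam)
    if pool_sparse:
        while expected.size > 3 and expected[-1] < 1.0:
            expected = np.concatenate([expected[:-2], [expected[-2] + expected[-1]]])
            observed = np.concatenate([observed[:-2], [observed[-2] + observed[-1]]])
    c = observed.size
    df = c - 1 - 1
    if df < 1:
        raise ValueError(
            f"only {c} count classes (df = {df}); pool classes or use wider bins"
        )
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    if method == "chi2":
        p = float(stats.chi2.sf(chi2, df=df))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        sims = rng.poisson(lam, size=(n_boot, n_bins))
        exceed = sum(_poisson_chi2(s) >= chi2 for s in sims if s.max() >= 1)
        p = (1.0 + exceed) / (n_boot + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PoissonFitResult(
        bin_cm=float("nan"), n_bins=n_bins, lambda_hat=lam,
        observed=observed.astype(int) if not pool_sparse else observed,
        expected=expected, chi2=chi2, df=df, p_value=p,
    )


def call_clusters(
    linkage_map: LinkageMap,
    target_system: str = "RT",
    max_gap_cm: float = 5.0,
) -> list[TECluster]:
    """Maximal runs of adjacent target markers closer than ``max_gap_cm``.

    Within each CG the target-system markers are taken in map order
    (markers of other systems in between are ignored); every consecutive
    gap must be strictly below the threshold and a cluster needs at least
    two members.  Span is last minus first member position.
    """
    clusters: list[TECluster] = []
    for cg in linkage_map.ordered_cgs:
        pos = cg.positions_cm
        targets = [
            (m, float(p))
            for m, p in zip(cg.markers, pos)
            if linkage_map.system_of.get(m) == target_system
        ]
        run: list[tuple[str, float]] = []
        for item in targets:
            if run and item[1] - run[-1][1] < max_gap_cm:
                run.append(item)
            else:
                if len(run) >= 2:
                    clusters.append(
                        TECluster(cg.name, [m for m, _ in run], run[-1][1] - run[0][1])
                    )
                run = [item]
        if len(run) >= 2:
            clusters.append(
                TECluster(cg.name, [m for m, _ in run], run[-1][1] - run[0][1])
            )
    return clusters


def copy_number(total_fragments: int, n_combinations: int) -> CopyNumberEstimate:
    """Element copy number as fragments per enzyme/primer combination."""
    if n_combinations < 1:
        raise ValueError("need at least one combination")
    if total_fragments < 0:
        raise ValueError("fragment count must be >= 0")
    return CopyNumberEstimate(total_fragments, n_combinations)


def copy_number_per_parent(
    parent1_fragments: int, parent2_fragments: int, n_combinations: int
) -> tuple[CopyNumberEstimate, CopyNumberEstimate]:
    """Per-parent copy numbers from parent-present fragment totals."""
    return (
        copy_number(parent1_fragments, n_combinations),
        copy_number(parent2_fragments, n_combinations),
    )
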