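"""Synthetic F1 outcross populations with known truth.

The raw genotype matrix behind the sugarcane map this package models was
never deposited, so every downstream stage is exercised against simulated
populations whose ground truth (marker placements, linkage phases, cross
types, planted retrotransposon clusters) is known exactly.

Meiosis model
-------------
Single-dose markers in a polyploid under faithful bivalent pairing transmit
like a diploid heterozygote: each parent passes one of two homologs per
chromosome, with crossovers as a no-interference (Poisson) process at one
event per 100 cM on the gamete, i.e. the Haldane recombination fraction
``r(d) = (1 - exp(-d/50)) / 2`` between loci ``d`` cM apart.  Band presence
follows the cross type: a D1 marker shows a band iff parent 1 transmits the
band-carrying homolog, D2 analogously for parent 2, and a C (simplex x
simplex) marker shows a band iff either parent does.  A single shared
genetic length per chromosome is used for both parental meioses, matching
the one-recombination-fraction-per-interval convention of an integrated map.

Defaults emulate the study population: 188 individuals, 730 single-dose
markers split over three marker systems and the D1/D2/C cross types in the
published proportions, and six planted clusters of retrotransposon-derived
markers.  The default genome mirrors the reported map structure — 92
linkage elements (one per mapped homolog) of 52.64 cM each, ~4843 cM in
total — rather than a handful of long chromosomes: in a high-polyploid the
single-dose markers of each homolog form their own small co-segregation
group, which is exactly the fragmentation the reference map shows
(2-39 markers per group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import (
    ABSENT,
    MISSING,
    PRESENT,
    MarkerSystem,
    MarkerTable,
    table_from_arrays,
)

CROSS_TYPES = ("D1", "D2", "C")

_AFLP_E = tuple(f"E{i}" for i in range(32, 46))
_AFLP_M = tuple(f"M{i}" for i in range(47, 63))
_RT_ENZYMES = ("AI", "DI", "SI", "RI")
_RT_PRIMERS = ("sIvSI", "sIvGR", "sIvLI", "sIvLII")
_SSR_PREFIXES = ("ESTA", "ESTB", "ESTC", "CV")


def haldane_rf(d_cm: float) -> float:
    """Recombination fraction between loci ``d_cm`` apart, no interference."""
    return 0.5 * (1.0 - math.exp(-d_cm / 50.0))


def default_marker_counts() -> dict[tuple[MarkerSystem, str], int]:
    """Single-dose marker counts per (system, cross type), study proportions."""
    return {
        (MarkerSystem.AFLP, "D1"): 197,
        (MarkerSystem.AFLP, "D2"): 192,
        (MarkerSystem.AFLP, "C"): 146,
        (MarkerSystem.EST_SSR, "D1"): 41,
        (MarkerSystem.EST_SSR, "D2"): 60,
        (MarkerSystem.EST_SSR, "C"): 29,
        (MarkerSystem.RT, "D1"): 23,
        (MarkerSystem.RT, "D2"): 32,
        (MarkerSystem.RT, "C"): 10,
    }


@dataclass(frozen=True)
class TEClusterSpec:
    """Planted retrotransposon-marker clusters.

    ``sizes`` gives markers per cluster (defaults mirror the six observed
    clusters of 2-3 markers); within-cluster adjacent gaps are drawn
    uniformly below ``spacing_cm``.  ``mode`` = ``"uniform"`` is the null:
    positions i.i.d. uniform, no clustering.
    """

    sizes: tuple[int, ...] = (3, 2, 2, 2, 3, 2)
    spacing_cm: float = 5.0
    mode: str = "clustered"

    def __post_init__(self):
        if self.mode not in ("clustered", "uniform"):
            raise ValueError(f"unknown TE placement mode {self.mode!r}")
        if self.spacing_cm <= 0:
            raise ValueError("spacing must be positive")
        if any(s < 2 for s in self.sizes):
            raise ValueError("clusters need >= 2 markers")


@dataclass(frozen=True)
class DistortedMarker:
    """An extra unlinked marker with a forced band-transmission bias."""

    cross_type: str = "D1"
    p_present: float = 0.9


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int = 188
    n_chromosomes: int = 92
    chromosome_length_cm: float = 52.64
    marker_counts: dict[tuple[MarkerSystem, str], int] = field(
        default_factory=default_marker_counts
    )
    te_clusters: TEClusterSpec = field(default_factory=TEClusterSpec)
    missing_rate: float = 0.05
    error_rate: float = 0.01
    distortion: tuple[DistortedMarker, ...] = ()
    n_homolog_groups: int = 8
    ssr_alleles_per_locus: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("need >= 2 individuals")
        if self.n_chromosomes < 1:
            raise ValueError("need >= 1 chromosome")
        if self.chromosome_length_cm < 0:
            raise ValueError("chromosome length must be >= 0")
        for rate in (self.missing_rate, self.error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if any(v < 0 for v in self.marker_counts.values()):
            raise ValueError("marker counts must be >= 0")
        if not 1 <= self.n_homolog_groups <= self.n_chromosomes:
            raise ValueError("n_homolog_groups must be in [1, n_chromosomes]")


@dataclass
class Placement:
    marker_id: str
    chromosome: int
    position_cm: float
    cross_type: str
    system: MarkerSystem
    phase_p1: int
    phase_p2: int
    ssr_locus: str | None = None
    te_cluster: int | None = None


@dataclass
class TrueMap:
    """Simulation ground truth: placements plus transmitted-homolog matrices."""

    chromosome_lengths: list[float]
    placements: list[Placement]
    homolog_group: list[int]
    #: (n_markers, n_individuals) transmitted P1 / P2 homolog per marker,
    #: aligned with ``placements`` order; -1 for unlinked distorted markers.
    transmitted_p1: np.ndarray | None = None
    transmitted_p2: np.ndarray | None = None

    def by_chromosome(self) -> list[list[Placement]]:
        out: list[list[Placement]] = [[] for _ in self.chromosome_lengths]
        for p in self.placements:
            if p.chromosome >= 0:
                out[p.chromosome].append(p)
        for chrom in out:
            chrom.sort(key=lambda p: p.position_cm)
        return out

    def placement(self, marker_id: str) -> Placement:
        for p in self.placements:
            if p.marker_id == marker_id:
                return p
        raise KeyError(marker_id)


def place_te_markers(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[tuple[int, float, int | None]]:
    """Positions for retrotransposon markers: (chromosome, position, cluster id).

    Clustered mode plants ``len(sizes)`` clusters at uniform centers with
    every within-cluster adjacent gap below ``spacing_cm``; leftover markers
    (and all markers in uniform mode) get i.i.d. uniform positions.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spec = config.te_clusters
    n_rt = sum(
        v for (sys_, _), v in config.marker_counts.items() if sys_ == MarkerSystem.RT
    )
    out: list[tuple[int, float, int | None]] = []
    if spec.mode == "clustered":
        clustered = sum(spec.sizes)
        if clustered > n_rt:
            raise ValueError(
                f"cluster spec needs {clustered} markers but only {n_rt} RT markers"
            )
        for ci, size in enumerate(spec.sizes):
            max_span = (size - 1) * spec.spacing_cm
            if max_span > config.chromosome_length_cm:
                raise ValueError("cluster span exceeds chromosome length")
            chrom = int(rng.integers(config.n_chromosomes))
            start = float(rng.uniform(0, config.chromosome_length_cm - max_span))
            gaps = rng.uniform(0.0, spec.spacing_cm, size=size - 1)
            pos = start + np.concatenate([[0.0], np.cumsum(gaps)])
            for p in pos:
                out.append((chrom, float(p), ci))
        n_rest = n_rt - clustered
    else:
        n_rest = n_rt
    for _ in range(n_rest):
        chrom = int(rng.integers(config.n_chromosomes))
        out.append((chrom, float(rng.uniform(0, config.chromosome_length_cm)), None))
    return out


def _unique_size(rng: np.random.Generator, used: set[str], code: str) -> int:
    while True:
        size = int(rng.integers(100, 1000))
        if f"{code}{size}" not in used:
            return size


def _build_placements(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[Placement], list[int]]:
    """Lay all markers on chromosomes; returns placements and homolog groups."""
    homolog_group = [c % config.n_homolog_groups for c in range(config.n_chromosomes)]
    hg_members: dict[int, list[int]] = {}
    for c, h in enumerate(homolog_group):
        hg_members.setdefault(h, []).append(c)

    placements: list[Placement] = []
    used_names: set[str] = set()

    def add(system, cross, chrom, pos, ssr_locus=None, te_cluster=None, code=None):
        if code is None:
            if system == MarkerSystem.AFLP:
                code = rng.choice(_AFLP_E) + rng.choice(_AFLP_M)
            else:
                code = rng.choice(_RT_ENZYMES) + rng.choice(_RT_PRIMERS)
        size = _unique_size(rng, used_names, code)
        used_names.add(f"{code}{size}")
        marker_id = f"{cross}-{code}{size}"
        placements.append(
            Placement(
                marker_id, chrom, pos, cross, system,
                int(rng.integers(2)), int(rng.integers(2)),
                ssr_locus=ssr_locus, te_cluster=te_cluster,
            )
        )

    # AFLP scaffold: uniform placements
    for cross in CROSS_TYPES:
        for _ in range(config.marker_counts.get((MarkerSystem.AFLP, cross), 0)):
            chrom = int(rng.integers(config.n_chromosomes))
            add(MarkerSystem.AFLP, cross, chrom,
                float(rng.uniform(0, config.chromosome_length_cm)))

    # EST-SSR loci: multiallelic, alleles of one locus spread across the
    # homologs of one homeology group (this is what makes them usable as
    # anchors for homo(eo)logous-group assembly).
    ssr_pool: list[str] = []
    for cross in CROSS_TYPES:
        ssr_pool += [cross] * config.marker_counts.get((MarkerSystem.EST_SSR, cross), 0)
    rng.shuffle(ssr_pool)
    n_loci = max(1, math.ceil(len(ssr_pool) / config.ssr_alleles_per_locus)) if ssr_pool else 0
    locus_codes = [
        f"{_SSR_PREFIXES[i % len(_SSR_PREFIXES)]}{i // len(_SSR_PREFIXES) + 1:02d}"
        for i in range(n_loci)
    ]
    idx = 0
    for li, locus in enumerate(locus_codes):
        hg = li % config.n_homolog_groups
        members = hg_members[hg]
        k = 0
        while idx < len(ssr_pool) and k < config.ssr_alleles_per_locus:
            cross = ssr_pool[idx]
            chrom = members[k % len(members)]
            add(
                MarkerSystem.EST_SSR, cross, chrom,
                float(rng.uniform(0, config.chromosome_length_cm)),
                ssr_locus=locus, code=locus,
            )
            idx += 1
            k += 1

    # retrotransposon markers: clustered (or uniform-null) placement
    rt_pool: list[str] = []
    for cross in CROSS_TYPES:
        rt_pool += [cross] * config.marker_counts.get((MarkerSystem.RT, cross), 0)
    rng.shuffle(rt_pool)
    te_positions = place_te_markers(config, rng)
    for cross, (chrom, pos, cluster) in zip(rt_pool, te_positions):
        add(MarkerSystem.RT, cross, chrom, pos, te_cluster=cluster)

    return placements, homolog_group


def simulate_population(config: SimulationConfig) -> tuple[MarkerTable, TrueMap]:
    """Simulate genotyping of an F1 population; returns scores plus truth.

    Deterministic for a fixed config (same seed, same output).  Scoring
    error flips each non-missing call with probability ``error_rate``;
    missingness masks calls with probability ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    placements, homolog_group = _build_placements(config, rng)
    n = config.n_individuals

    by_chrom: list[list[int]] = [[] for _ in range(config.n_chromosomes)]
    for i, p in enumerate(placements):
        by_chrom[p.chromosome].append(i)
    for lst in by_chrom:
        lst.sort(key=lambda i: placements[i].position_cm)

    m = len(placements)
    A = np.zeros((m, n), dtype=np.int8)  # transmitted P1 homolog
    B = np.zeros((m, n), dtype=np.int8)  # transmitted P2 homolog
    for chrom_markers in by_chrom:
        if not chrom_markers:
            continue
        pos = np.array([placements[i].position_cm for i in chrom_markers])
        for trans in (A, B):
            state = rng.integers(0, 2, size=n).astype(np.int8)
            trans[chrom_markers[0]] = state
            for prev, cur in zip(chrom_markers[:-1], chrom_markers[1:]):
                d = placements[cur].position_cm - placements[prev].position_cm
                r = haldane_rf(d)
                flip = rng.random(n) < r
                state = np.where(flip, 1 - state, state).astype(np.int8)
                trans[cur] = state
        del pos

    bands = np.zeros((m, n), dtype=bool)
    for i, p in enumerate(placements):
        from_p1 = A[i] == p.phase_p1
        from_p2 = B[i] == p.phase_p2
        if p.cross_type == "D1":
            bands[i] = from_p1
        elif p.cross_type == "D2":
            bands[i] = from_p2
        else:
            bands[i] = from_p1 | from_p2

    # distorted extras: unlinked loci with a forced transmission bias
    for k, d in enumerate(config.distortion):
        placements.append(
            Placement(f"{d.cross_type}-DIST{k + 1}x{900 + k}", -1, float("nan"),
                      d.cross_type, MarkerSystem.AFLP, 0, 0)
        )
        bands = np.vstack([bands, rng.random(n) < d.p_present])
        A = np.vstack([A, np.full(n, -1, dtype=np.int8)])
        B = np.vstack([B, np.full(n, -1, dtype=np.int8)])
        m += 1

    scores = np.where(bands, PRESENT, ABSENT).astype(np.int8)
    if config.error_rate > 0:
        flips = rng.random(scores.shape) < config.error_rate
        scores = np.where(flips, 1 - scores, scores).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(scores.shape) < config.missing_rate
        scores[mask] = MISSING

    parent1 = [PRESENT if p.cross_type in ("D1", "C") else ABSENT for p in placements]
    parent2 = [PRESENT if p.cross_type in ("D2", "C") else ABSENT for p in placements]
    individuals = [f"F1_{i + 1:03d}" for i in range(n)]
    table = table_from_arrays(
        individuals,
        [p.marker_id for p in placements],
        [p.system for p in placements],
        parent1,
        parent2,
        scores,
    )
    truth = TrueMap(
        chromosome_lengths=[config.chromosome_length_cm] * config.n_chromosomes,
        placements=placements,
        homolog_group=homolog_group,
        transmitted_p1=A,
        transmitted_p2=B,
    )
    return table, truth


def write_truth(truth: TrueMap, path) -> None:
    """Sidecar TSV of the simulation ground truth."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("marker\tchromosome\tposition_cM\tcross_type\tsystem\t"
                 "phase_p1\tphase_p2\tssr_locus\tte_cluster\n")
        for p in truth.placements:
            fh.write(
                f"{p.marker_id}\t{p.chromosome}\t{p.position_cm:.4f}\t{p.cross_type}\t"
                f"{p.system.value}\t{p.phase_p1}\t{p.phase_p2}\t"
                f"{p.ssr_locus or '-'}\t{p.te_cluster if p.te_cluster is not None else '-'}\n"
            )


@dataclass(frozen=True)
class NBSProfileConfig:
    """Simulated anchored-PCR fingerprints of a multi-copy element.

    Each enzyme/primer combination detects each of ``true_copy_number``
    genomic copies independently with ``detection_prob``; a detected copy
    is absent from a given parent with probability ``polymorphism_rate/2``
    (insertion polymorphism between the two parents).
    """

    true_copy_number: int = 60
    n_combinations: int = 6
    detection_prob: float = 0.99
    polymorphism_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.true_copy_number < 1 or self.n_combinations < 1:
            raise ValueError("copy number and combinations must be positive")
        if not 0.0 < self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in (0, 1]")
        if not 0.0 <= self.polymorphism_rate <= 1.0:
            raise ValueError("polymorphism_rate must be in [0, 1]")


@dataclass
class NBSProfileResult:
    band_counts: np.ndarray          # per combination, all detected fragments
    parent1_counts: np.ndarray       # per combination, fragments present in P1
    parent2_counts: np.ndarray

    @property
    def total_fragments(self) -> int:
        return int(self.band_counts.sum())


def simulate_nbs_profiles(config: NBSProfileConfig) -> NBSProfileResult:
    rng = np.random.default_rng(config.seed)
    k, c = config.n_combinations, config.true_copy_number
    detected = rng.random((k, c)) < config.detection_prob
    absent1 = rng.random((k, c)) < config.polymorphism_rate / 2.0
    absent2 = rng.random((k, c)) < config.polymorphism_rate / 2.0
    return NBSProfileResult(
        band_counts=detected.sum(axis=1),
        parent1_counts=(detected & ~absent1).sum(axis=1),
        parent2_counts=(detected & ~absent2).sum(axis=1),
    )


def small_config(**overrides) -> SimulationConfig:
    """A desk-scale configuration for quick tests: 5 chromosomes, 100 markers."""
    counts = {
        (MarkerSystem.AFLP, "D1"): 27,
        (MarkerSystem.AFLP, "D2"): 26,
        (MarkerSystem.AFLP, "C"): 20,
        (MarkerSystem.EST_SSR, "D1"): 6,
        (MarkerSystem.EST_SSR, "D2"): 8,
        (MarkerSystem.EST_SSR, "C"): 4,
        (MarkerSystem.RT, "D1"): 3,
        (MarkerSystem.RT, "D2"): 4,
        (MarkerSystem.RT, "C"): 2,
    }
    base = dict(
        n_chromosomes=5,
        chromosome_length_cm=150.0,
        marker_counts=counts,
        te_clusters=TEClusterSpec(sizes=(3, 2), spacing_cm=5.0),
        n_homolog_groups=2,
    )
    base.update(overrides)
    return SimulationConfig(**base)
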