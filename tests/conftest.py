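import numpy as np
import pytest

from canemap.io import ABSENT, PRESENT, MarkerSystem, table_from_arrays
from canemap.simulate import SimulationConfig, TEClusterSpec, haldane_rf


def tiny_config(seed=0, **overrides):
    """3 chromosomes x 50 cM, ~33 markers: fast pipeline smoke tests."""
    counts = {
        (MarkerSystem.AFLP, "D1"): 8,
        (MarkerSystem.AFLP, "D2"): 8,
        (MarkerSystem.AFLP, "C"): 6,
        (MarkerSystem.EST_SSR, "D1"): 2,
        (MarkerSystem.EST_SSR, "D2"): 2,
        (MarkerSystem.EST_SSR, "C"): 2,
        (MarkerSystem.RT, "D1"): 2,
        (MarkerSystem.RT, "D2"): 2,
        (MarkerSystem.RT, "C"): 1,
    }
    base = dict(
        n_chromosomes=3,
        chromosome_length_cm=50.0,
        marker_counts=counts,
        te_clusters=TEClusterSpec(sizes=(2,), spacing_cm=5.0),
        n_homolog_groups=1,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def toy_table():
    """3 markers x 4 individuals, one of each cross type."""
    scores = np.array(
        [
            [1, 0, 1, 0],
            [0, 1, 0, -1],
            [1, 1, 1, 0],
        ],
        dtype=np.int8,
    )
    return table_from_arrays(
        ["i1", "i2", "i3", "i4"],
        ["D1-E35M47510", "D2-DIsIvLI385", "C-ESTB94279"],
        [MarkerSystem.AFLP, MarkerSystem.RT, MarkerSystem.EST_SSR],
        [PRESENT, ABSENT, PRESENT],
        [ABSENT, PRESENT, PRESENT],
        scores,
    )


def simulate_chain(
    seed,
    crosses,
    spacing_cm=10.0,
    n=188,
    phases=None,
    error_rate=0.0,
    missing_rate=0.0,
):
    """Hand-rolled single-chromosome F1 simulation, independent of the
    package's generator: equally spaced markers, Haldane crossovers.

    Returns (table, marker_ids, transmitted_p1, transmitted_p2, phases).
    """
    rng = np.random.default_rng(seed)
    L = len(crosses)
    if phases is None:
        ph1 = rng.integers(2, size=L)
        ph2 = rng.integers(2, size=L)
    else:
        ph1, ph2 = phases
    A = np.zeros((L, n), dtype=np.int8)
    B = np.zeros((L, n), dtype=np.int8)
    r = haldane_rf(spacing_cm)
    for T in (A, B):
        s = rng.integers(2, size=n)
        T[0] = s
        for i in range(1, L):
            flip = rng.random(n) < r
            s = np.where(flip, 1 - s, s)
            T[i] = s
    bands = np.zeros((L, n), dtype=bool)
    for i, c in enumerate(crosses):
        f1 = A[i] == ph1[i]
        f2 = B[i] == ph2[i]
        bands[i] = f1 if c == "D1" else (f2 if c == "D2" else (f1 | f2))
    scores = np.where(bands, PRESENT, ABSENT).astype(np.int8)
    if error_rate > 0:
        flips = rng.random(scores.shape) < error_rate
        scores = np.where(flips, 1 - scores, scores).astype(np.int8)
    if missing_rate > 0:
        scores[rng.random(scores.shape) < missing_rate] = -1
    ids = [f"{c}-M{i + 1}x{100 + i}" for i, c in enumerate(crosses)]
    table = table_from_arrays(
        [f"I{k:03d}" for k in range(n)],
        ids,
        [MarkerSystem.AFLP] * L,
        [PRESENT if c in ("D1", "C") else ABSENT for c in crosses],
        [PRESENT if c in ("D2", "C") else ABSENT for c in crosses],
        scores,
    )
    return table, ids, A, B, (ph1, ph2)
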