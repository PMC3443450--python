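"""Cross-type classification and segregation-ratio testing of dominant markers.

In an outcrossed F1 between two highly heterozygous (polyploid) parents,
single-dose dominant markers fall into three informative configurations:

* ``D1`` — band heterozygous in parent 1 only (simplex x nulliplex),
  expected to segregate 1:1 (present:absent) in the progeny;
* ``D2`` — heterozygous in parent 2 only, also 1:1;
* ``C``  — simplex in both parents, segregating 3:1.

Each genotyped locus is tested against its expected ratio with a plain
Pearson chi-square (1 df); the family of tests is controlled with a
Bonferroni correction, and distorted loci are excluded from linkage
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ABSENT, MISSING, PRESENT, MarkerTable

CROSS_D1 = "D1"
CROSS_D2 = "D2"
CROSS_C = "C"
CROSS_INVALID = "invalid"

RATIO_1_1 = "1:1"
RATIO_3_1 = "3:1"

_EXPECTED_PRESENT = {RATIO_1_1: 0.5, RATIO_3_1: 0.75}


@dataclass
class SegregationResult:
    marker_id: str
    cross_type: str
    expected_ratio: str | None
    n_present: int
    n_absent: int
    chi2: float
    p_value: float
    kept: bool
    reason: str = ""


@dataclass(frozen=True)
class BonferroniThreshold:
    alpha_global: float
    n_tests: int

    @property
    def alpha_per_test(self) -> float:
        return self.alpha_global / self.n_tests


def classify_cross_type(parent1_band: int, parent2_band: int) -> tuple[str, str | None]:
    """Map parental band scores to a cross type and expected progeny ratio."""
    if parent1_band == MISSING or parent2_band == MISSING:
        return CROSS_INVALID, None
    if parent1_band == PRESENT and parent2_band == ABSENT:
        return CROSS_D1, RATIO_1_1
    if parent1_band == ABSENT and parent2_band == PRESENT:
        return CROSS_D2, RATIO_1_1
    if parent1_band == PRESENT and parent2_band == PRESENT:
        return CROSS_C, RATIO_3_1
    return CROSS_INVALID, None  # absent x absent: no segregating allele


def chisq_segregation(n_present: int, n_absent: int, ratio: str) -> tuple[float, float]:
    """Pearson chi-square (1 df) of observed band counts against 1:1 or 3:1."""
    total = n_present + n_absent
    if total < 1:
        raise ValueError("no scored progeny")
    p = _EXPECTED_PRESENT[ratio]
    exp_present = total * p
    exp_absent = total * (1.0 - p)
    chi2 = (n_present - exp_present) ** 2 / exp_present + (
        n_absent - exp_absent
    ) ** 2 / exp_absent
    p_value = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p_value


def bonferroni_alpha(alpha_global: float, n_tests: int) -> BonferroniThreshold:
    if alpha_global <= 0 or alpha_global > 1:
        raise ValueError("alpha_global must be in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return BonferroniThreshold(alpha_global, n_tests)


def filter_sdm(
    table: MarkerTable, alpha_global: float = 0.05
) -> tuple[list[SegregationResult], pd.DataFrame]:
    """Classify and test every marker; keep undistorted single-dose markers.

    The number of Bonferroni tests is the number of markers with a valid
    cross type and at least one non-missing progeny score.  Missing progeny
    scores are dropped from the counts, never imputed.  Returns per-marker
    results and a summary table of counts per marker system
    (scorable / segregating / SDM / D1 / D2 / C / kept).
    """
    prelim: list[SegregationResult] = []
    for rec in table.records:
        cross, ratio = classify_cross_type(rec.parent1_band, rec.parent2_band)
        n_present = int(np.sum(rec.scores == PRESENT))
        n_absent = int(np.sum(rec.scores == ABSENT))
        if cross == CROSS_INVALID:
            prelim.append(
                SegregationResult(
                    rec.marker_id, cross, None, n_present, n_absent,
                    np.nan, np.nan, False, reason="no valid parental configuration",
                )
            )
        elif n_present + n_absent == 0:
            prelim.append(
                SegregationResult(
                    rec.marker_id, cross, ratio, 0, 0, np.nan, np.nan, False,
                    reason="no scored progeny",
                )
            )
        else:
            chi2, p = chisq_segregation(n_present, n_absent, ratio)
            prelim.append(
                SegregationResult(rec.marker_id, cross, ratio, n_present, n_absent,
                                  chi2, p, True)
            )
    testable = [r for r in prelim if r.reason == "" and r.cross_type != CROSS_INVALID]
    n_tests = len(testable)
    if n_tests:
        thr = bonferroni_alpha(alpha_global, n_tests)
        for r in testable:
            if r.p_value < thr.alpha_per_test:
                r.kept = False
                r.reason = "segregation distortion"
    summary = _table1_summary(table, prelim)
    return prelim, summary


def _table1_summary(table: MarkerTable, results: list[SegregationResult]) -> pd.DataFrame:
    """Counts per marker system in the style of a genotyping summary table."""
    by_id = {r.marker_id: r for r in results}
    rows = {}
    systems = sorted({rec.system.value for rec in table.records})
    for system in systems + ["Total"]:
        recs = [
            rec for rec in table.records if system == "Total" or rec.system.value == system
        ]
        res = [by_id[rec.marker_id] for rec in recs]
        sdm = [r for r in res if r.kept]
        rows[system] = {
            "scorable": len(recs),
            "segregating": sum(1 for r in res if r.cross_type != CROSS_INVALID),
            "SDM": len(sdm),
            "D1": sum(1 for r in sdm if r.cross_type == CROSS_D1),
            "D2": sum(1 for r in sdm if r.cross_type == CROSS_D2),
            "C": sum(1 for r in sdm if r.cross_type == CROSS_C),
            "excluded_distorted": sum(1 for r in res if r.reason == "segregation distortion"),
        }
    return pd.DataFrame(rows).T


def results_frame(results: list[SegregationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker": [r.marker_id for r in results],
            "cross_type": [r.cross_type for r in results],
            "ratio": [r.expected_ratio or "-" for r in results],
            "n_present": [r.n_present for r in results],
            "n_absent": [r.n_absent for r in results],
            "chi2": [r.chi2 for r in results],
            "p_value": [r.p_value for r in results],
            "kept": [r.kept for r in results],
            "reason": [r.reason for r in results],
        }
    )
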